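"""Generative model of the spatial latent-cause detection task.

On each trial a binary category ``C`` is drawn. When ``C = 0`` all ``N``
points are uniform on a disc of radius ``R``. When ``C = 1`` a hidden source
location ``mu`` is drawn from an isotropic Gaussian centred on the park
centre with standard deviation ``sigma_s``; each point is independently
affiliated with the source with probability ``p_aff``, affiliated points are
Gaussian around ``mu`` with standard deviation ``sigma``, and unaffiliated
points are uniform on the disc. If any generated point falls outside the
disc the whole stimulus (category, source, affiliations and points) is
redrawn; at the default parameters this is rare.

Coordinates are continuous Cartesian "park units" with the origin at the
park centre (default radius 10). Any display scaling is presentation-only
and never enters computation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TaskParams",
    "Trial",
    "sample_trial",
    "sample_session",
    "trials_to_frame",
    "frame_to_trials",
    "write_trials_csv",
    "read_trials_csv",
    "write_trials_jsonl",
    "read_trials_jsonl",
    "load_task_config",
]

DEFAULT_N_SET = (6, 9, 12, 15)


@dataclass(frozen=True)
class TaskParams:
    """Constants of the generative model.

    Defaults equal the experiment: ``p_aff = 0.5``, ``R = 10`` park units,
    ``sigma_s = 2`` (spread of the source around the centre), ``sigma = 2``
    (spread of affiliated points around the source), ``p_C1 = 0.5`` and set
    sizes ``N in {6, 9, 12, 15}``.
    """

    p_aff: float = 0.5
    R: float = 10.0
    sigma_s: float = 2.0
    sigma: float = 2.0
    p_C1: float = 0.5
    N_set: tuple[int, ...] = DEFAULT_N_SET

    def __post_init__(self) -> None:
        for name in ("p_aff", "R", "sigma_s", "sigma", "p_C1"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if not 0.0 <= self.p_aff <= 1.0:
            raise ValueError(f"p_aff must lie in [0, 1], got {self.p_aff}")
        if not 0.0 <= self.p_C1 <= 1.0:
            raise ValueError(f"p_C1 must lie in [0, 1], got {self.p_C1}")
        if self.R <= 0 or self.sigma_s <= 0 or self.sigma <= 0:
            raise ValueError("R, sigma_s and sigma must be positive")
        object.__setattr__(self, "N_set", tuple(int(n) for n in self.N_set))
        if len(self.N_set) == 0:
            raise ValueError("N_set must not be empty")
        if any(n < 1 for n in self.N_set):
            raise ValueError("every N in N_set must be >= 1")


@dataclass
class Trial:
    """A single stimulus: ``N`` points on the disc with optional ground truth.

    ``points`` is an ``(N, 2)`` float array. ``C``, ``mu`` and ``z`` are the
    generative ground truth and are absent (``None``) for observer-facing
    data; ``C = 0`` trials never carry ``mu`` or ``z``.
    """

    points: np.ndarray
    C: Optional[int] = None
    mu: Optional[np.ndarray] = None
    z: Optional[np.ndarray] = None
    trial_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array")
        if self.mu is not None:
            self.mu = np.asarray(self.mu, dtype=float).reshape(2)
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=int).reshape(-1)
            if self.z.shape[0] != self.N:
                raise ValueError("z must have one entry per point")
        if self.C == 0 and (self.mu is not None or self.z is not None):
            raise ValueError("C = 0 trials carry no mu or z")

    @property
    def N(self) -> int:
        return self.points.shape[0]

    @property
    def n_affiliated(self) -> Optional[int]:
        return None if self.z is None else int(self.z.sum())


def _sample_uniform_disc(R: float, size: int, rng: np.random.Generator) -> np.ndarray:
    # Inverse-CDF in radius: r = R * sqrt(u) gives the uniform disc.
    r = R * np.sqrt(rng.uniform(size=size))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=size)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def sample_trial(params: TaskParams, N: int, rng: np.random.Generator) -> Trial:
    """Draw one stimulus, rejecting and redrawing the whole trial if any
    point leaves the disc."""
    if N < 1:
        raise ValueError("N must be >= 1")
    while True:
        C = int(rng.uniform() < params.p_C1)
        if C == 0:
            points = _sample_uniform_disc(params.R, N, rng)
            # uniform-disc points cannot leave the disc; no rejection needed
            return Trial(points=points, C=0)
        mu = rng.normal(0.0, params.sigma_s, size=2)
        z = (rng.uniform(size=N) < params.p_aff).astype(int)
        points = _sample_uniform_disc(params.R, N, rng)
        n1 = int(z.sum())
        if n1:
            points[z == 1] = mu + rng.normal(0.0, params.sigma, size=(n1, 2))
        if np.all(np.einsum("ij,ij->i", points, points) < params.R**2):
            return Trial(points=points, C=1, mu=mu, z=z)
        # else: reject the entire stimulus (including C, mu, z) and redraw


def sample_session(
    params: TaskParams, n_trials: int, rng: np.random.Generator
) -> list[Trial]:
    """Draw ``n_trials`` i.i.d. trials; ``N`` uniform over ``params.N_set``."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if len(params.N_set) == 0:
        raise ValueError("N_set must not be empty")
    Ns = rng.choice(np.asarray(params.N_set), size=n_trials)
    trials = [sample_trial(params, int(n), rng) for n in Ns]
    for i, t in enumerate(trials):
        t.trial_id = i
    return trials


# ---------------------------------------------------------------------------
# Trial-table I/O.
#
# CSV (wide) format: one row per trial with columns
#   trial_id, N, C, mu_x, mu_y, z, x1_x, x1_y, ..., xM_x, xM_y
# where M = max N in the table; unused point columns, and mu/z on C=0 or
# unlabelled trials, are left empty. z is a bitstring such as "010011".
# The JSON-lines dialect has one object per line with the same field names
# and a "points" key holding an [[x, y], ...] list.
# ---------------------------------------------------------------------------


def trials_to_frame(trials: Sequence[Trial]) -> pd.DataFrame:
    max_n = max(t.N for t in trials)
    rows = []
    for i, t in enumerate(trials):
        row: dict = {
            "trial_id": t.trial_id if t.trial_id is not None else i,
            "N": t.N,
            "C": t.C if t.C is not None else pd.NA,
            "mu_x": t.mu[0] if t.mu is not None else np.nan,
            "mu_y": t.mu[1] if t.mu is not None else np.nan,
            "z": "".join(map(str, t.z)) if t.z is not None else pd.NA,
        }
        for j in range(max_n):
            if j < t.N:
                row[f"x{j + 1}_x"] = t.points[j, 0]
                row[f"x{j + 1}_y"] = t.points[j, 1]
            else:
                row[f"x{j + 1}_x"] = np.nan
                row[f"x{j + 1}_y"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_trials(df: pd.DataFrame) -> list[Trial]:
    trials = []
    for _, row in df.iterrows():
        n = int(row["N"])
        pts = np.array(
            [[row[f"x{j + 1}_x"], row[f"x{j + 1}_y"]] for j in range(n)], dtype=float
        )
        C = None if pd.isna(row.get("C")) else int(row["C"])
        mu = None
        if "mu_x" in row and not pd.isna(row["mu_x"]):
            mu = np.array([row["mu_x"], row["mu_y"]], dtype=float)
        z = None
        zval = row.get("z")
        if zval is not None and not pd.isna(zval) and str(zval) != "":
            s = str(zval)
            if s.endswith(".0"):  # bitstring parsed as a number upstream
                s = s[:-2]
            if len(s) < n and set(s) <= {"0", "1"}:
                s = s.zfill(n)  # numeric parsing drops leading zeros
            if len(s) != n or not set(s) <= {"0", "1"}:
                raise ValueError(f"cannot parse affiliation bitstring {zval!r}")
            z = np.array([int(c) for c in s], dtype=int)
        trials.append(
            Trial(points=pts, C=C, mu=mu, z=z, trial_id=int(row["trial_id"]))
        )
    return trials


def write_trials_csv(trials: Sequence[Trial], path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def read_trials_csv(path) -> list[Trial]:
    # z is a bitstring ("010011"); keep it textual so leading zeros survive
    return frame_to_trials(pd.read_csv(path, dtype={"z": "string"}))


def write_trials_jsonl(trials: Sequence[Trial], path) -> None:
    with open(path, "w") as fh:
        for i, t in enumerate(trials):
            obj = {
                "trial_id": t.trial_id if t.trial_id is not None else i,
                "N": t.N,
                "C": t.C,
                "mu_x": None if t.mu is None else float(t.mu[0]),
                "mu_y": None if t.mu is None else float(t.mu[1]),
                "z": None if t.z is None else "".join(map(str, t.z)),
                "points": t.points.tolist(),
            }
            fh.write(json.dumps(obj) + "\n")


def read_trials_jsonl(path) -> list[Trial]:
    trials = []
    with open(path) as fh:
        for line in fh:
            obj = json.loads(line)
            mu = None
            if obj.get("mu_x") is not None:
                mu = np.array([obj["mu_x"], obj["mu_y"]], dtype=float)
            z = None
            if obj.get("z"):
                z = np.array([int(c) for c in obj["z"]], dtype=int)
            trials.append(
                Trial(
                    points=np.asarray(obj["points"], dtype=float),
                    C=obj.get("C"),
                    mu=mu,
                    z=z,
                    trial_id=obj.get("trial_id"),
                )
            )
    return trials


def load_task_config(path) -> tuple[TaskParams, Optional[int]]:
    """Read TaskParams (and an optional ``seed``) from a YAML or JSON file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    seed = cfg.pop("seed", None)
    if "N_set" in cfg:
        cfg["N_set"] = tuple(cfg["N_set"])
    return TaskParams(**cfg), seed
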