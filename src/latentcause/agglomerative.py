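"""Agglomerative cluster search for the source-present partition.

A greedy alternative to enumerating all 2^N affiliation patterns: grow a
single candidate cluster from a seed point, scoring each candidate partition
by the marginal-likelihood ratio

    LLR(z) = log L(z) - log L0,

i.e. the evidence that the cluster points came from the Gaussian source
(marginalising its location) and the rest from the uniform background,
against the all-background hypothesis. Growth adds the nearest non-member
point (by default nearest to the current cluster centroid, recomputed after
each addition) and stops at the first strict decrease of the LLR. The sweep
runs every point as the seed, making the algorithm deterministic, and keeps
the best partition across seeds. The total number of LLR evaluations —
at most N per seed, so at most N^2 overall — doubles as a reaction-time
proxy for the observer.

The LLR excludes the partition prior p(z) by default, mirroring the
commit-to-z evidence integral; ``include_partition_prior=True`` adds it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .inference import InternalModel, log_L0, log_L_given_z, log_partition_prior
from .task import Trial

__all__ = ["ACResult", "ACOptions", "ac_cluster", "ac_iterations_as_rt"]


@dataclass(frozen=True)
class ACOptions:
    growth: str = "centroid"  # "centroid" | "seed" | "any_member"
    include_partition_prior: bool = False
    keep_traces: bool = False


@dataclass
class ACResult:
    best_llr: float
    best_z: np.ndarray
    n_evaluations: int
    per_seed_trace: Optional[list] = None

    @property
    def mu_hat(self) -> np.ndarray:
        """Mean of the committed cluster (the joint point estimate of mu)."""
        return self._points[self.best_z == 1].mean(axis=0)

    _points: np.ndarray = field(default=None, repr=False)


def _next_index(points, members, candidates, growth):
    if growth == "centroid":
        ref = points[members].mean(axis=0)
        d = ((points[candidates] - ref) ** 2).sum(axis=1)
    elif growth == "seed":
        ref = points[members[0]]
        d = ((points[candidates] - ref) ** 2).sum(axis=1)
    elif growth == "any_member":
        d = (
            ((points[candidates][:, None, :] - points[members][None, :, :]) ** 2)
            .sum(axis=2)
            .min(axis=1)
        )
    else:
        raise ValueError(f"unknown growth rule {growth!r}")
    return candidates[int(np.argmin(d))]  # argmin ties -> lowest index


def ac_cluster(
    trial, model: InternalModel, options: Optional[ACOptions] = None
) -> ACResult:
    """Run the seed-swept greedy cluster search on one trial."""
    opts = options or ACOptions()
    points = trial.points if isinstance(trial, Trial) else np.atleast_2d(trial)
    n = points.shape[0]
    if n == 0:
        raise ValueError("trial has no points")
    base = log_L0(points, model)
    p_aff = model.p_aff_for(n)

    def llr(z):
        out = log_L_given_z(z, points, model) - base
        if opts.include_partition_prior:
            out += log_partition_prior(z, p_aff)
        return out

    best_llr = -np.inf
    best_z = None
    n_evals = 0
    traces = [] if opts.keep_traces else None
    for seed in range(n):
        members = [seed]
        z = np.zeros(n, dtype=int)
        z[seed] = 1
        cur = llr(z)
        n_evals += 1
        seed_best, seed_best_z = cur, z.copy()
        trace = [cur]
        while len(members) < n:
            candidates = np.setdiff1d(np.arange(n), members, assume_unique=False)
            nxt = _next_index(points, members, candidates, opts.growth)
            z[nxt] = 1
            members.append(nxt)
            new = llr(z)
            n_evals += 1
            trace.append(new)
            if new < cur:  # strict decrease stops growth; ties continue
                break
            cur = new
            if new > seed_best:  # running max over the seed's trajectory
                seed_best, seed_best_z = new, z.copy()
        if traces is not None:
            traces.append((seed, trace))
        if seed_best > best_llr:
            best_llr, best_z = seed_best, seed_best_z
    return ACResult(
        best_llr=float(best_llr),
        best_z=best_z,
        n_evaluations=n_evals,
        per_seed_trace=traces,
        _points=points,
    )


def ac_iterations_as_rt(results: list[ACResult]) -> np.ndarray:
    """Evaluation counts per trial, for binning against decision-variable
    quantiles as a reaction-time proxy."""
    return np.array([r.n_evaluations for r in results], dtype=int)
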