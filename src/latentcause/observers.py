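"""The observer-model zoo: evidence approximations and decision variables.

Each observer turns a stimulus into a decision variable

    d = log L~1 - log L0,

where ``L~1`` approximates the source-present evidence. Families differ in
which nuisance variables of the generative model they marginalise versus
commit to as point estimates:

* Family A marginalises both the source location ``mu`` and the affiliation
  pattern ``z`` (the full Bayesian evidence).
* Family B commits to a single ``mu_hat`` (centroid, peak kernel density, or
  posterior mean) and sums over ``z``; the evidence then factorises as a
  product of per-point Gaussian/uniform mixtures.
* Family C commits to a single ``z_hat`` (maximum marginal likelihood,
  maximum marginal posterior, or the greedy agglomerative search) and
  marginalises ``mu`` in closed form.
* Family D commits to both (joint posterior or joint likelihood maximisers,
  the agglomerative search with the cluster mean, or a radial-threshold rule
  around a committed ``mu_hat``).
* Family H uses no generative-model variables at all: a scalar heuristic
  statistic f(x) (pairwise distances, nearest-neighbour distances, kernel
  density) is compared against a criterion directly.

The committed-value evidences for the maximum-marginal-posterior and
maximum-joint-posterior strategies include the prior factors of the
quantities they maximised (``p(z)`` resp. ``p(mu)``); the resulting d is not
a calibrated log posterior ratio, which the fitted decision criterion
absorbs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np

from .agglomerative import ACOptions, ac_cluster
from .inference import (
    InternalModel,
    PARTITION_CAP,
    _log_bernoulli,
    _log_L_given_z_all,
    _suff_stats,
    log_L0,
    log_L1_exact,
    log_L_given_mu,
    log_joint_likelihood,
    partition_matrix,
    posterior_mean_mu,
)
from .task import Trial

__all__ = [
    "ObserverSpec",
    "CommitResult",
    "decision_variable",
    "heuristic_statistic",
    "threshold_radius",
    "kernel_density_map",
    "CATALOGUE",
    "RESULTS_ALIASES",
    "METHODS_ALIASES",
    "resolve_model_id",
    "DensityGrid",
]

_FAMILY_STRATEGIES = {
    "A": {"bayes"},
    "B": {"centroid", "max_density", "pme"},
    "C": {"mml", "mmp", "ac"},
    "D": {"mjp", "mjl", "ac", "centroid_threshold", "density_threshold"},
    "H": {"h10", "h11", "h12", "h13", "h14"},
}


@dataclass(frozen=True)
class ObserverSpec:
    """Which family/strategy an observer uses, plus fitting flexibility flags."""

    family: str
    strategy: str
    flexible_criteria_by_N: bool = False
    flexible_p_aff_by_N: bool = False
    flexible_sigmas: bool = False

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_STRATEGIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.strategy not in _FAMILY_STRATEGIES[self.family]:
            raise ValueError(
                f"strategy {self.strategy!r} is not valid for family {self.family}"
            )
        if self.flexible_sigmas and not (
            self.family == "A" and self.strategy == "bayes"
        ):
            raise ValueError("flexible_sigmas is only available for the Bayesian model")


@dataclass
class CommitResult:
    """Point estimates an observer committed to, and the search cost."""

    mu_hat: Optional[np.ndarray] = None
    z_hat: Optional[np.ndarray] = None
    n_evaluations: int = 1


# Canonical catalogue. Every B/C/D model is fitted with N-dependent criteria
# (the task's alternative models all carry that flexibility); the Bayesian
# model comes in a single-criterion (A1) and an N-dependent-criterion (A2)
# variant, plus a flexible-belief variant (A3). Heuristic models always use
# per-N criteria.
CATALOGUE: dict[str, ObserverSpec] = {
    "A1": ObserverSpec("A", "bayes"),
    "A2": ObserverSpec("A", "bayes", flexible_criteria_by_N=True),
    "A3": ObserverSpec("A", "bayes", flexible_criteria_by_N=True, flexible_sigmas=True),
    "B4": ObserverSpec("B", "centroid", flexible_criteria_by_N=True),
    "B5": ObserverSpec("B", "max_density", flexible_criteria_by_N=True),
    "B6": ObserverSpec("B", "pme", flexible_criteria_by_N=True),
    "C_mml": ObserverSpec("C", "mml", flexible_criteria_by_N=True),
    "C_mmp": ObserverSpec("C", "mmp", flexible_criteria_by_N=True),
    "C_ac": ObserverSpec("C", "ac", flexible_criteria_by_N=True),
    "D_mjp": ObserverSpec("D", "mjp", flexible_criteria_by_N=True),
    "D_mjl": ObserverSpec("D", "mjl", flexible_criteria_by_N=True),
    "D_ac": ObserverSpec("D", "ac", flexible_criteria_by_N=True),
    "D13": ObserverSpec("D", "centroid_threshold", flexible_criteria_by_N=True),
    "D14": ObserverSpec("D", "density_threshold", flexible_criteria_by_N=True),
    "H10": ObserverSpec("H", "h10", flexible_criteria_by_N=True),
    "H11": ObserverSpec("H", "h11", flexible_criteria_by_N=True),
    "H12": ObserverSpec("H", "h12", flexible_criteria_by_N=True),
    "H13": ObserverSpec("H", "h13", flexible_criteria_by_N=True),
    "H14": ObserverSpec("H", "h14", flexible_criteria_by_N=True),
}

# The source publication numbers models differently in its Results and
# Methods sections; both alias tables map onto the canonical IDs above.
RESULTS_ALIASES = {
    "C7": "C_mml",
    "C8": "C_ac",
    "D9": "D_mjp",
    "D10": "D_mjl",
    "D11": "D_ac",
}
METHODS_ALIASES = {
    "C(8)": "C_mml",
    "C(9)": "C_ac",
    "D(10)": "D_mjp",
    "D(11)": "D_mjl",
    "D(12)": "D_ac",
    "D(13)": "D13",
    "D(14)": "D14",
}


def resolve_model_id(model_id: str) -> tuple[str, ObserverSpec]:
    """Resolve a catalogue ID or alias, with an optional trailing ``P`` for
    the N-dependent-affiliation-belief variants; returns (canonical_id, spec).
    """
    base = model_id
    flexible_p = False
    if base.endswith("P") and base not in CATALOGUE:
        base, flexible_p = base[:-1], True
    base = RESULTS_ALIASES.get(base, METHODS_ALIASES.get(base, base))
    if base not in CATALOGUE:
        raise KeyError(f"unknown observer model {model_id!r}")
    spec = CATALOGUE[base]
    if flexible_p:
        if spec.family == "H":
            raise ValueError("heuristic models have no affiliation belief")
        spec = ObserverSpec(
            spec.family,
            spec.strategy,
            spec.flexible_criteria_by_N,
            True,
            spec.flexible_sigmas,
        )
        return base + "P", spec
    return base, spec


# ---------------------------------------------------------------------------
# Kernel density map (shared by the max-density commitment and the
# max-local-density heuristic).
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DensityGrid:
    """Square evaluation grid spanning [-R, R]^2 (141 x 141 by default)."""

    n_nodes: int = 141

    @lru_cache(maxsize=4)
    def axes(self, R: float) -> np.ndarray:
        return np.linspace(-R, R, self.n_nodes)


def kernel_density_map(points: np.ndarray, R: float, kernel_width: float,
                       grid: Optional[DensityGrid] = None):
    """Sum of isotropic Gaussian kernels evaluated on the arena grid.

    Returns (density values (G^2,), grid locations (G^2, 2)). Densities are a
    sum (not an average) of normalised 2-D Gaussian kernels, so a single
    point peaks at 1 / (2 pi kernel_width^2).
    """
    g = (grid or DensityGrid()).axes(R)
    gx, gy = np.meshgrid(g, g, indexing="ij")
    locs = np.column_stack([gx.ravel(), gy.ravel()])
    d2 = ((locs[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
    dens = (np.exp(-d2 / (2 * kernel_width**2)) / (2 * np.pi * kernel_width**2)).sum(
        axis=1
    )
    return dens, locs


def _max_density_location(points: np.ndarray, model: InternalModel) -> np.ndarray:
    dens, locs = kernel_density_map(points, model.R, model.sigma)
    return locs[int(np.argmax(dens))]  # argmax ties -> lowest linear index


def threshold_radius(model: InternalModel) -> float:
    """Distance from a committed source at which the affiliated Gaussian
    density equals the uniform background density: the ML affiliation rule
    assigns a point to the cluster iff it is closer than

        r* = sqrt(2 sigma^2 log(R^2 / (2 sigma^2))).

    Returns 0 (with a warning) when R^2 <= 2 sigma^2, where the Gaussian
    never beats the background.
    """
    ratio = model.R**2 / (2 * model.sigma**2)
    if ratio <= 1.0:
        warnings.warn(
            "R^2 <= 2 sigma^2: the Gaussian density never exceeds the "
            "uniform background; threshold radius is 0",
            stacklevel=2,
        )
        return 0.0
    return math.sqrt(2 * model.sigma**2 * math.log(ratio))


# ---------------------------------------------------------------------------
# Heuristic statistics (Family H).
# ---------------------------------------------------------------------------


def _pairwise_distances(x: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist

    return pdist(x)


def _nn_distances(x: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import squareform

    d = squareform(_pairwise_distances(x))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def heuristic_statistic(
    strategy: str,
    trial,
    kernel_width: Optional[float] = None,
    threshold: Optional[float] = None,
    model: Optional[InternalModel] = None,
) -> float:
    """Scalar stimulus statistic f(x) for the heuristic observers.

    h10: negative mean pairwise distance. h11: maximum of the Gaussian-kernel
    local density over the arena grid. h12: negative minimum pairwise
    distance. h13: negative mean nearest-neighbour distance. h14: fraction of
    points whose nearest-neighbour distance falls below ``threshold``
    (default: the radial affiliation threshold r*).
    """
    model = model or InternalModel()
    x = trial.points if isinstance(trial, Trial) else np.atleast_2d(trial)
    if strategy != "h11" and x.shape[0] < 2:
        raise ValueError(f"{strategy} needs at least two points")
    if strategy == "h10":
        return float(-_pairwise_distances(x).mean())
    if strategy == "h11":
        width = kernel_width if kernel_width is not None else model.sigma
        dens, _ = kernel_density_map(x, model.R, width)
        return float(dens.max())
    if strategy == "h12":
        return float(-_pairwise_distances(x).min())
    if strategy == "h13":
        return float(-_nn_distances(x).mean())
    if strategy == "h14":
        thr = threshold if threshold is not None else threshold_radius(model)
        return float((_nn_distances(x) < thr).mean())
    raise ValueError(f"unknown heuristic {strategy!r}")


# ---------------------------------------------------------------------------
# Committed-partition argmax helpers (deterministic tie-breaking: smallest
# N1, then lexicographic z).
# ---------------------------------------------------------------------------


def _argmax_partition(values: np.ndarray, Z: np.ndarray) -> int:
    best = values.max()
    ties = np.flatnonzero(values == best)
    if len(ties) == 1:
        return int(ties[0])
    n1 = Z[ties].sum(axis=1)
    order = sorted(
        range(len(ties)), key=lambda i: (n1[i], tuple(Z[ties[i]].astype(int)))
    )
    return int(ties[order[0]])


def decision_variable(
    spec: ObserverSpec,
    trial,
    model: Optional[InternalModel] = None,
    ac_options: Optional[ACOptions] = None,
) -> tuple[float, CommitResult]:
    """Decision variable d = log L~1 - log L0 (or f(x) for Family H) and the
    committed point estimates. Deterministic given (trial, model)."""
    model = model or InternalModel()
    x = trial.points if isinstance(trial, Trial) else np.atleast_2d(trial)
    n = x.shape[0]
    base = log_L0(x, model)
    p_aff = model.p_aff_for(n)

    if spec.family == "H":
        return heuristic_statistic(spec.strategy, x, model=model), CommitResult()

    if spec.family == "A":
        d = log_L1_exact(x, model) - base
        return float(d), CommitResult(n_evaluations=2**n)

    if spec.family == "B":
        if spec.strategy == "centroid":
            mu_hat = x.mean(axis=0)
            n_eval = 1
        elif spec.strategy == "max_density":
            mu_hat = _max_density_location(x, model)
            n_eval = DensityGrid().n_nodes ** 2
        elif spec.strategy == "pme":
            mu_hat = posterior_mean_mu(x, model)
            n_eval = 2**n
        d = log_L_given_mu(mu_hat, x, model) - base
        return float(d), CommitResult(mu_hat=mu_hat, n_evaluations=n_eval)

    if spec.family == "C":
        if spec.strategy == "ac":
            res = ac_cluster(x, model, ac_options)
            return res.best_llr, CommitResult(
                z_hat=res.best_z, n_evaluations=res.n_evaluations
            )
        log_lz, N1, _ = _log_L_given_z_all(x, model)
        Z = partition_matrix(n)
        if spec.strategy == "mml":
            idx = _argmax_partition(log_lz, Z)
            d = log_lz[idx] - base
        else:  # mmp: include the partition prior in both the argmax and L~1
            scored = log_lz + _log_bernoulli(N1, n - N1, p_aff)
            idx = _argmax_partition(scored, Z)
            d = scored[idx] - base
        return float(d), CommitResult(
            z_hat=Z[idx].astype(int), n_evaluations=2**n
        )

    # Family D
    s2, ss2 = model.sigma**2, model.sigma_s**2
    log_prior_mu_const = -math.log(2 * math.pi * ss2)

    def joint_at(z, mu):
        return log_joint_likelihood(z, mu, x, model)

    if spec.strategy in ("mjp", "mjl"):
        Z = partition_matrix(n)
        N1, x_sum, sq_sum = _suff_stats(x, Z)
        if spec.strategy == "mjp":
            # inner mu-argmax is the posterior-kernel mean m(x, z)
            mu_star = x_sum / (N1 + s2 / ss2)[:, None]
        else:
            # inner mu-argmax of the bare likelihood: the cluster mean
            with np.errstate(invalid="ignore", divide="ignore"):
                mu_star = np.where(
                    (N1 > 0)[:, None], x_sum / np.maximum(N1, 1)[:, None], 0.0
                )
        sq_dev = sq_sum - 2 * (mu_star * x_sum).sum(axis=1) + N1 * (
            mu_star**2
        ).sum(axis=1)
        vals = (
            -(n - N1) * math.log(math.pi * model.R**2)
            - N1 * math.log(2 * math.pi * s2)
            - sq_dev / (2 * s2)
        )
        if spec.strategy == "mjp":
            vals = vals + log_prior_mu_const - (mu_star**2).sum(axis=1) / (2 * ss2)
        idx = _argmax_partition(vals, Z)
        z_hat = Z[idx].astype(int)
        mu_hat = mu_star[idx]
        d = vals[idx] - base
        return float(d), CommitResult(
            mu_hat=mu_hat, z_hat=z_hat, n_evaluations=2**n
        )

    if spec.strategy == "ac":
        res = ac_cluster(x, model, ac_options)
        z_hat = res.best_z
        mu_hat = x[z_hat == 1].mean(axis=0)
        d = joint_at(z_hat, mu_hat) - base
        return float(d), CommitResult(
            mu_hat=mu_hat, z_hat=z_hat, n_evaluations=res.n_evaluations
        )

    if spec.strategy in ("centroid_threshold", "density_threshold"):
        if spec.strategy == "centroid_threshold":
            mu_hat = x.mean(axis=0)
        else:
            mu_hat = _max_density_location(x, model)
        r_star = threshold_radius(model)
        z_hat = (((x - mu_hat) ** 2).sum(axis=1) < r_star**2).astype(int)
        d = joint_at(z_hat, mu_hat) - base
        return float(d), CommitResult(mu_hat=mu_hat, z_hat=z_hat, n_evaluations=1)

    raise ValueError(f"unknown strategy {spec.strategy!r}")
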