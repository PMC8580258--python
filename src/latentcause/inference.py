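"""Exact likelihood machinery for the latent-cause generative model.

The category evidences are

    L0 = (pi R^2)^{-N}                               (all points background)
    L1 = sum_z integral L(z, mu) p(z) p(mu) dmu      (source present)

where ``z`` ranges over all 2^N affiliation patterns and ``mu`` over source
locations. Marginalising ``mu`` for a fixed partition has a closed form
because the affiliated points contribute a product of isotropic Gaussians
that collapses to a single (unnormalised) Gaussian in ``mu``:

    L(z) = (pi R^2)^{-N0} * w~(x, z)
    w~   = [1 + (sigma_s^2/sigma^2) N1]^{-1} (2 pi sigma^2)^{-N1}
           * exp( -[sq_sum - ||x_sum||^2 / (N1 + sigma^2/sigma_s^2)]
                  / (2 sigma^2) )

with ``x_sum``/``sq_sum`` the sum and squared-norm sum of affiliated points.
The posterior over ``mu`` is then a 2^N-component mixture of isotropic
Gaussians with means ``m(z) = x_sum / (N1 + sigma^2/sigma_s^2)`` and
variances ``v(z) = 1 / (1/sigma_s^2 + N1/sigma^2)``. Everything is done in
natural-log space with log-sum-exp.

The Gaussian's truncation by the disc boundary is ignored throughout, as in
the task's observer models (points leaving the disc are exceedingly rare at
the default parameters).

Exact enumeration is capped at ``N <= PARTITION_CAP`` (2^20 terms); a 2-D
quadrature route over ``mu`` — O(N * grid) with no 2^N term — is provided as
an independent computation of the same evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Optional, Union

import numpy as np
from scipy.special import logsumexp

from .task import TaskParams, Trial

__all__ = [
    "InternalModel",
    "PartitionStats",
    "PosteriorMixture",
    "PARTITION_CAP",
    "partition_matrix",
    "log_L0",
    "log_partition_prior",
    "log_joint_likelihood",
    "log_L_given_z",
    "log_L_given_mu",
    "log_L1_exact",
    "log_L1_quadrature",
    "posterior_mu_mixture",
    "posterior_mean_mu",
    "partition_table",
]

PARTITION_CAP = 20

PAffLike = Union[float, Mapping[int, float]]


@dataclass(frozen=True)
class InternalModel:
    """The observer's internal beliefs about the generative constants.

    Defaults equal the true task parameters. ``p_aff`` may be a scalar or a
    per-set-size map ``{N: p}`` (the "false belief" variants); ``sigma`` and
    ``sigma_s`` are free in the flexible-belief Bayesian variant.
    """

    p_aff: PAffLike = 0.5
    sigma: float = 2.0
    sigma_s: float = 2.0
    R: float = 10.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.sigma_s <= 0 or self.R <= 0:
            raise ValueError("sigma, sigma_s and R must be positive")
        for p in self._p_aff_values():
            if not (0.0 <= p <= 1.0) or not math.isfinite(p):
                raise ValueError(f"p_aff must lie in [0, 1], got {p}")

    def _p_aff_values(self):
        if isinstance(self.p_aff, Mapping):
            return list(self.p_aff.values())
        return [self.p_aff]

    def p_aff_for(self, N: int) -> float:
        if isinstance(self.p_aff, Mapping):
            try:
                return float(self.p_aff[N])
            except KeyError:
                raise KeyError(f"p_aff map has no entry for N = {N}") from None
        return float(self.p_aff)

    @classmethod
    def from_task(cls, params: TaskParams) -> "InternalModel":
        return cls(
            p_aff=params.p_aff, sigma=params.sigma, sigma_s=params.sigma_s, R=params.R
        )


@dataclass
class PartitionStats:
    """Sufficient statistics of one affiliation pattern."""

    z: np.ndarray
    N1: int
    N0: int
    x_sum: np.ndarray
    sq_sum: float

    @classmethod
    def from_points(cls, z: np.ndarray, points: np.ndarray) -> "PartitionStats":
        z = np.asarray(z, dtype=int)
        mask = z == 1
        n1 = int(mask.sum())
        x_sum = points[mask].sum(axis=0) if n1 else np.zeros(2)
        sq_sum = float((points[mask] ** 2).sum()) if n1 else 0.0
        return cls(z=z, N1=n1, N0=len(z) - n1, x_sum=x_sum, sq_sum=sq_sum)


@dataclass
class PosteriorMixture:
    """Mixture-of-Gaussians posterior over the source location ``mu``.

    ``log_weights`` are unnormalised (log of p(z) * (pi R^2)^{-N0} * w~);
    ``log_normalizer`` is their log-sum-exp, which equals log L1.
    """

    log_weights: np.ndarray
    means: np.ndarray  # (K, 2)
    variances: np.ndarray  # (K,), isotropic
    log_normalizer: float

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.log_weights - self.log_normalizer)

    def pdf(self, mu: np.ndarray) -> np.ndarray:
        """Posterior density at one or many locations (last axis = 2)."""
        mu = np.asarray(mu, dtype=float)
        pts = np.atleast_2d(mu.reshape(-1, 2))
        d2 = ((pts[:, None, :] - self.means[None, :, :]) ** 2).sum(axis=2)
        log_comp = (
            -np.log(2 * np.pi * self.variances)[None, :]
            - d2 / (2 * self.variances)[None, :]
        )
        out = np.exp(
            logsumexp(log_comp + self.log_weights[None, :], axis=1)
            - self.log_normalizer
        )
        return out.reshape(mu.shape[:-1]) if mu.ndim > 1 else float(out[0])

    def mean(self) -> np.ndarray:
        w = self.weights
        return w @ self.means


@lru_cache(maxsize=8)
def partition_matrix(N: int) -> np.ndarray:
    """All 2^N binary affiliation vectors as a (2^N, N) float array."""
    if N > PARTITION_CAP:
        raise ValueError(
            f"N = {N} exceeds the exact-enumeration cap ({PARTITION_CAP}); "
            "use log_L1_quadrature instead"
        )
    codes = np.arange(2**N, dtype=np.int64)
    return ((codes[:, None] >> np.arange(N)) & 1).astype(float)


def _points(trial) -> np.ndarray:
    if isinstance(trial, Trial):
        return trial.points
    return np.atleast_2d(np.asarray(trial, dtype=float))


def log_L0(trial, model: InternalModel) -> float:
    """Log evidence of the all-background category: -N log(pi R^2)."""
    n = _points(trial).shape[0] if np.size(_points(trial)) else 0
    return -n * math.log(math.pi * model.R**2)


def _log_bernoulli(n1, n0, p_aff: float) -> np.ndarray:
    """N1 log p + N0 log(1-p), with -inf for impossible patterns at p in {0,1}."""
    if not 0.0 <= p_aff <= 1.0:
        raise ValueError(f"p_aff must lie in [0, 1], got {p_aff}")
    n1 = np.asarray(n1, dtype=float)
    n0 = np.asarray(n0, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(n1 > 0, n1 * np.log(p_aff), 0.0)
        t0 = np.where(n0 > 0, n0 * np.log1p(-p_aff), 0.0)
    return t1 + t0


def log_partition_prior(z, p_aff: float) -> float:
    """Log prior of an affiliation pattern under i.i.d. Bernoulli(p_aff)."""
    z = np.asarray(z, dtype=int)
    n1 = int(z.sum())
    return float(_log_bernoulli(n1, len(z) - n1, p_aff))


def log_joint_likelihood(z, mu, trial, model: InternalModel) -> float:
    """log L(z, mu): background points uniform, affiliated points Gaussian."""
    x = _points(trial)
    z = np.asarray(z, dtype=int)
    if z.shape[0] != x.shape[0]:
        raise ValueError("z must have one entry per point")
    mu = np.asarray(mu, dtype=float).reshape(2)
    n0 = int((z == 0).sum())
    out = -n0 * math.log(math.pi * model.R**2)
    mask = z == 1
    if mask.any():
        d2 = ((x[mask] - mu) ** 2).sum(axis=1)
        out += float(
            (-np.log(2 * np.pi * model.sigma**2) - d2 / (2 * model.sigma**2)).sum()
        )
    return out


def _suff_stats(x: np.ndarray, Z: np.ndarray):
    """Vectorised sufficient statistics for a stack of partitions."""
    N1 = Z.sum(axis=1)
    x_sum = Z @ x  # (M, 2)
    sq_sum = Z @ (x**2).sum(axis=1)  # (M,)
    return N1, x_sum, sq_sum


def _log_w_tilde(N1, x_sum, sq_sum, model: InternalModel):
    """log w~(x, z): the mu-marginal of the affiliated Gaussian product."""
    s2, ss2 = model.sigma**2, model.sigma_s**2
    quad = sq_sum - (x_sum**2).sum(axis=-1) / (N1 + s2 / ss2)
    return (
        -np.log1p((ss2 / s2) * N1)
        - N1 * math.log(2 * math.pi * s2)
        - quad / (2 * s2)
    )


def _log_L_given_z_all(x: np.ndarray, model: InternalModel):
    """log L(z) for every partition; returns (logL, N1, x_sum)."""
    Z = partition_matrix(x.shape[0])
    N1, x_sum, sq_sum = _suff_stats(x, Z)
    log_l = -(x.shape[0] - N1) * math.log(math.pi * model.R**2) + _log_w_tilde(
        N1, x_sum, sq_sum, model
    )
    return log_l, N1, x_sum


def log_L_given_z(z, trial, model: InternalModel) -> float:
    """Closed-form log L(z) = -N0 log(pi R^2) + log w~(x, z)."""
    x = _points(trial)
    st = PartitionStats.from_points(z, x)
    s2, ss2 = model.sigma**2, model.sigma_s**2
    quad = st.sq_sum - float((st.x_sum**2).sum()) / (st.N1 + s2 / ss2)
    lw = (
        -math.log1p((ss2 / s2) * st.N1)
        - st.N1 * math.log(2 * math.pi * s2)
        - quad / (2 * s2)
    )
    return -st.N0 * math.log(math.pi * model.R**2) + lw


def log_L_given_mu(mu, trial, model: InternalModel) -> float:
    """log L(mu) = sum_i log[(1-p_aff)/(pi R^2) + p_aff N(x_i; mu, sigma^2 I)]."""
    x = _points(trial)
    p = model.p_aff_for(x.shape[0])
    mu = np.asarray(mu, dtype=float).reshape(2)
    d2 = ((x - mu) ** 2).sum(axis=1)
    gauss = np.exp(-d2 / (2 * model.sigma**2)) / (2 * np.pi * model.sigma**2)
    return float(np.log((1 - p) / (np.pi * model.R**2) + p * gauss).sum())


def log_L1_exact(trial, model: InternalModel) -> float:
    """Log evidence of the source-present category by 2^N enumeration."""
    x = _points(trial)
    if x.shape[0] > PARTITION_CAP:
        raise ValueError(
            f"N = {x.shape[0]} exceeds the exact-enumeration cap "
            f"({PARTITION_CAP}); use log_L1_quadrature instead"
        )
    log_l, N1, _ = _log_L_given_z_all(x, model)
    log_prior = _log_bernoulli(N1, x.shape[0] - N1, model.p_aff_for(x.shape[0]))
    return float(logsumexp(log_prior + log_l))


@dataclass(frozen=True)
class GridSpec:
    """Tensor quadrature grid over mu, in units of sigma_s half-widths."""

    half_width_sigmas: float = 5.0
    n_nodes: int = 201

    def nodes(self, sigma_s: float):
        if self.n_nodes < 3 or self.half_width_sigmas <= 0:
            raise ValueError("degenerate quadrature grid")
        g = np.linspace(
            -self.half_width_sigmas * sigma_s,
            self.half_width_sigmas * sigma_s,
            self.n_nodes,
        )
        w = np.full(self.n_nodes, g[1] - g[0])
        w[[0, -1]] /= 2.0  # trapezoid
        return g, w


def log_L1_quadrature(
    trial, model: InternalModel, grid_spec: Optional[GridSpec] = None
) -> float:
    """Log evidence of the source-present category by 2-D quadrature over mu.

    Integrates exp(log L(mu)) against the Gaussian prior on mu on a tensor
    trapezoid grid; O(N * grid) with no 2^N term, so it serves as an
    independent route to the same quantity as :func:`log_L1_exact`.
    """
    x = _points(trial)
    spec = grid_spec or GridSpec()
    g, w = spec.nodes(model.sigma_s)
    gx, gy = np.meshgrid(g, g, indexing="ij")
    mu_grid = np.column_stack([gx.ravel(), gy.ravel()])  # (G^2, 2)
    p = model.p_aff_for(x.shape[0])
    d2 = ((mu_grid[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)  # (G^2, N)
    gauss = np.exp(-d2 / (2 * model.sigma**2)) / (2 * np.pi * model.sigma**2)
    log_l_mu = np.log((1 - p) / (np.pi * model.R**2) + p * gauss).sum(axis=1)
    log_prior = (
        -np.log(2 * np.pi * model.sigma_s**2)
        - (mu_grid**2).sum(axis=1) / (2 * model.sigma_s**2)
    )
    log_wts = np.log(np.outer(w, w).ravel())
    return float(logsumexp(log_l_mu + log_prior + log_wts))


def posterior_mu_mixture(trial, model: InternalModel) -> PosteriorMixture:
    """Posterior over the source location as a 2^N Gaussian mixture."""
    x = _points(trial)
    n = x.shape[0]
    if n > PARTITION_CAP:
        raise ValueError(f"N = {n} exceeds the exact-enumeration cap")
    Z = partition_matrix(n)
    N1, x_sum, sq_sum = _suff_stats(x, Z)
    s2, ss2 = model.sigma**2, model.sigma_s**2
    log_w = (
        _log_bernoulli(N1, n - N1, model.p_aff_for(n))
        - (n - N1) * math.log(math.pi * model.R**2)
        + _log_w_tilde(N1, x_sum, sq_sum, model)
    )
    means = x_sum / (N1 + s2 / ss2)[:, None]
    variances = 1.0 / (1.0 / ss2 + N1 / s2)
    return PosteriorMixture(
        log_weights=log_w,
        means=means,
        variances=variances,
        log_normalizer=float(logsumexp(log_w)),
    )


def posterior_mean_mu(trial, model: InternalModel) -> np.ndarray:
    """Posterior-mean source location (weights handled in log space)."""
    return posterior_mu_mixture(trial, model).mean()


def partition_table(trial, model: InternalModel):
    """Per-partition debug table: z, log p(z), log L(z), mean, variance.

    Returns a pandas DataFrame; intended for small N and CSV dumps.
    """
    import pandas as pd

    x = _points(trial)
    n = x.shape[0]
    mix = posterior_mu_mixture(trial, model)
    Z = partition_matrix(n).astype(int)
    N1 = Z.sum(axis=1)
    log_prior = _log_bernoulli(N1, n - N1, model.p_aff_for(n))
    return pd.DataFrame(
        {
            "z": ["".join(map(str, row)) for row in Z],
            "N1": N1,
            "log_prior": log_prior,
            "log_L_given_z": mix.log_weights - log_prior,
            "m_x": mix.means[:, 0],
            "m_y": mix.means[:, 1],
            "v": mix.variances,
        }
    )
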