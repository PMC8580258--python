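"""Stochastic response model: criterion, decision noise, and lapse.

A decision variable ``d`` is reported as "source present" when, after adding
zero-mean Gaussian noise with standard deviation ``sigma_d``, it exceeds a
criterion ``k`` (possibly set-size dependent). With a lapse probability
``lambda`` the observer instead guesses either category with probability
one half:

    p(report present | d) = lambda/2 + (1 - lambda) Phi((d - k_N) / sigma_d).

Reading Phi(d; k, sigma_d^2) as the probability that the noisy decision
variable exceeds the criterion is numerically identical to reading it as the
normal CDF at ``d`` with mean ``k``. The heuristic observers' printed
response rule omits the lapse terms; ``with_lapse=False`` reproduces it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.stats import norm

from .inference import InternalModel
from .observers import ObserverSpec, decision_variable

__all__ = ["ObserverParams", "response_probability", "simulate_responses"]

CriterionLike = Union[float, Mapping[int, float]]


@dataclass(frozen=True)
class ObserverParams:
    """Fitted response-stage parameters (plus optional internal beliefs).

    ``k`` is the decision criterion in log-ratio units, either one scalar or
    a map N -> k_N. ``sigma_d`` is the decision-noise SD (log-ratio units),
    ``lapse`` the probability of a random 50/50 guess. ``p_aff_internal``
    (scalar or per-N map) and ``sigma_internal``/``sigma_s_internal`` are
    carried for the false-belief and flexible-belief variants.
    """

    k: CriterionLike = 0.0
    sigma_d: float = 1.0
    lapse: float = 0.0
    p_aff_internal: Union[float, Mapping[int, float]] = 0.5
    sigma_internal: float = 2.0
    sigma_s_internal: float = 2.0

    def __post_init__(self) -> None:
        if self.sigma_d <= 0:
            raise ValueError("sigma_d must be positive")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must lie in [0, 1]")

    def k_for(self, N: int) -> float:
        if isinstance(self.k, Mapping):
            try:
                return float(self.k[N])
            except KeyError:
                raise KeyError(f"criterion map has no entry for N = {N}") from None
        return float(self.k)

    def internal_model(self, R: float = 10.0) -> InternalModel:
        return InternalModel(
            p_aff=self.p_aff_internal,
            sigma=self.sigma_internal,
            sigma_s=self.sigma_s_internal,
            R=R,
        )


def response_probability(
    d, params: ObserverParams, N: Optional[int] = None, with_lapse: bool = True
):
    """Probability of reporting "source present" given decision variable d."""
    d = np.asarray(d, dtype=float)
    if isinstance(params.k, Mapping):
        if N is None:
            raise ValueError("N is required with per-set-size criteria")
        k = params.k_for(int(N)) if np.isscalar(N) else np.array(
            [params.k_for(int(n)) for n in np.asarray(N).ravel()]
        ).reshape(np.shape(N))
    else:
        k = float(params.k)
    core = norm.cdf((d - k) / params.sigma_d)
    if with_lapse:
        out = 0.5 * params.lapse + (1.0 - params.lapse) * core
    else:
        out = core
    return float(out) if np.ndim(out) == 0 else out


def simulate_responses(
    spec: ObserverSpec,
    params: ObserverParams,
    trials: Sequence,
    rng: np.random.Generator,
    model: Optional[InternalModel] = None,
    with_lapse: bool = True,
):
    """Simulate binary responses for a list of trials.

    Computes each trial's decision variable under ``spec``, then draws the
    response from the lapse/noise/criterion psychometric rule. Returns
    ``(responses, d_values)`` as int and float arrays.
    """
    model = model or params.internal_model()
    d = np.array([decision_variable(spec, t, model)[0] for t in trials])
    Ns = np.array([t.N for t in trials])
    p = np.array(
        [
            response_probability(di, params, N=int(ni), with_lapse=with_lapse)
            for di, ni in zip(d, Ns)
        ]
    )
    responses = (rng.uniform(size=len(trials)) < p).astype(int)
    return responses, d
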