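"""Maximum-likelihood fitting and information-criterion model comparison.

The central objects follow the Model/Results convention: an
:class:`ObserverChoiceModel` is built from a trial list and the binary
responses of one subject (real or simulated), and its :meth:`fit` returns an
:class:`ObserverFitResults` carrying the estimates, the maximised Bernoulli
log-likelihood, AIC/BIC and a ``summary()`` table.

Free parameters by model:

* single-criterion models: {k, sigma_d, lapse};
* flexible-criterion variants: {k_N per set size, sigma_d, lapse};
* "P" variants add one internal affiliation probability per set size;
* the flexible-belief Bayesian variant adds {sigma, sigma_s};
* heuristic models: {k_N per set size, sigma_d} with no lapse.

Decision variables depend only on the stimulus and the observer's internal
beliefs, so for fixed beliefs they are computed once per trial and cached;
criterion/noise/lapse refits then never re-run inference. Fits of the
belief-flexible variants recompute the decision variables inside the
objective. Optimisation is multi-start Nelder-Mead from Latin-hypercube
draws, with ``lapse`` on the logit scale, ``sigma_d`` and the belief sigmas
on the log scale, and criteria unbounded.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .inference import InternalModel
from .observers import ObserverSpec, decision_variable, resolve_model_id
from .response import ObserverParams, response_probability
from .task import TaskParams, sample_session

__all__ = [
    "ObserverChoiceModel",
    "ObserverFitResults",
    "FitResult",
    "negative_log_likelihood",
    "fit_model",
    "compare_models",
    "parameter_recovery",
    "model_recovery",
]

_P_CLIP = 1e-12


from scipy.special import expit as _expit


def _logit(p):
    return float(np.log(p) - np.log1p(-p))


def _dataset_fingerprint(trials, responses) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(responses, dtype=np.int8).tobytes())
    for t in trials[: min(len(trials), 50)]:
        h.update(np.ascontiguousarray(t.points, dtype=float).tobytes())
    h.update(str(len(trials)).encode())
    return h.hexdigest()


def _bernoulli_nll(p: np.ndarray, responses: np.ndarray) -> float:
    p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    return float(-(responses * np.log(p) + (1 - responses) * np.log1p(-p)).sum())


def negative_log_likelihood(
    model_id: str,
    params: ObserverParams,
    trials: Sequence,
    responses,
    d_values: Optional[np.ndarray] = None,
    R: float = 10.0,
) -> float:
    """Bernoulli negative log-likelihood of the responses under one observer.

    ``d_values`` may carry precomputed decision variables (one per trial);
    otherwise they are computed from ``params``' internal beliefs. Response
    probabilities are clipped to [1e-12, 1 - 1e-12].
    """
    canonical, spec = resolve_model_id(model_id)
    responses = np.asarray(responses, dtype=int)
    if len(responses) != len(trials):
        raise ValueError("responses must align with trials")
    if d_values is None:
        model = params.internal_model(R=R)
        d_values = np.array([decision_variable(spec, t, model)[0] for t in trials])
    Ns = np.array([t.N for t in trials])
    with_lapse = spec.family != "H"
    p = np.array(
        [
            response_probability(d, params, N=int(n), with_lapse=with_lapse)
            for d, n in zip(d_values, Ns)
        ]
    )
    return _bernoulli_nll(p, responses)


@dataclass
class ObserverFitResults:
    """Estimates and fit diagnostics for one observer model on one dataset."""

    model_id: str
    params: ObserverParams
    n_params: int
    log_lik: float
    aic: float
    bic: float
    n_trials: int
    n_restarts: int
    converged: bool
    seed: Optional[int] = None
    dataset_fingerprint: str = ""
    param_names: tuple = ()
    param_values: tuple = ()

    @property
    def llf(self) -> float:
        return self.log_lik

    def summary(self) -> str:
        lines = [
            f"Observer choice model: {self.model_id}",
            "=" * 44,
            f"{'n trials':<22}{self.n_trials:>22}",
            f"{'free parameters':<22}{self.n_params:>22}",
            f"{'log-likelihood':<22}{self.log_lik:>22.3f}",
            f"{'AIC':<22}{self.aic:>22.3f}",
            f"{'BIC':<22}{self.bic:>22.3f}",
            f"{'restarts':<22}{self.n_restarts:>22}",
            f"{'converged':<22}{str(self.converged):>22}",
            "-" * 44,
        ]
        for name, val in zip(self.param_names, self.param_values):
            lines.append(f"{name:<22}{val:>22.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "n_params": self.n_params,
            "log_lik": self.log_lik,
            "aic": self.aic,
            "bic": self.bic,
            "n_trials": self.n_trials,
            "n_restarts": self.n_restarts,
            "converged": self.converged,
            "seed": self.seed,
            "params": dict(zip(self.param_names, map(float, self.param_values))),
        }


FitResult = ObserverFitResults


class _ParamLayout:
    """Maps the optimiser vector onto ObserverParams for one model."""

    def __init__(self, spec: ObserverSpec, n_set: tuple[int, ...]):
        self.spec = spec
        self.n_set = tuple(sorted(n_set))
        names: list[str] = []
        if spec.flexible_criteria_by_N:
            names += [f"k_{n}" for n in self.n_set]
        else:
            names += ["k"]
        names += ["sigma_d"]
        if spec.family != "H":
            names += ["lapse"]
        if spec.flexible_p_aff_by_N:
            names += [f"p_aff_{n}" for n in self.n_set]
        if spec.flexible_sigmas:
            names += ["sigma", "sigma_s"]
        self.names = names
        self.n_free = len(names)
        self.needs_inference = spec.flexible_p_aff_by_N or spec.flexible_sigmas

    # transformed (unconstrained) <-> natural scale
    def to_natural(self, theta: np.ndarray) -> dict:
        out, i = {}, 0
        if self.spec.flexible_criteria_by_N:
            out["k"] = {n: float(theta[i + j]) for j, n in enumerate(self.n_set)}
            i += len(self.n_set)
        else:
            out["k"] = float(theta[i])
            i += 1
        out["sigma_d"] = float(np.exp(theta[i]))
        i += 1
        if self.spec.family != "H":
            out["lapse"] = float(_expit(theta[i]))
            i += 1
        else:
            out["lapse"] = 0.0
        if self.spec.flexible_p_aff_by_N:
            out["p_aff_internal"] = {
                n: float(_expit(theta[i + j])) for j, n in enumerate(self.n_set)
            }
            i += len(self.n_set)
        else:
            out["p_aff_internal"] = 0.5
        if self.spec.flexible_sigmas:
            out["sigma_internal"] = float(np.exp(theta[i]))
            out["sigma_s_internal"] = float(np.exp(theta[i + 1]))
            i += 2
        else:
            out["sigma_internal"] = 2.0
            out["sigma_s_internal"] = 2.0
        return out

    def natural_values(self, nat: dict) -> tuple:
        vals = []
        if self.spec.flexible_criteria_by_N:
            vals += [nat["k"][n] for n in self.n_set]
        else:
            vals += [nat["k"]]
        vals += [nat["sigma_d"]]
        if self.spec.family != "H":
            vals += [nat["lapse"]]
        if self.spec.flexible_p_aff_by_N:
            vals += [nat["p_aff_internal"][n] for n in self.n_set]
        if self.spec.flexible_sigmas:
            vals += [nat["sigma_internal"], nat["sigma_s_internal"]]
        return tuple(float(v) for v in vals)

    def start_bounds(self) -> list[tuple[float, float]]:
        b: list[tuple[float, float]] = []
        n_crit = len(self.n_set) if self.spec.flexible_criteria_by_N else 1
        b += [(-5.0, 10.0)] * n_crit  # criteria, log-ratio units
        b += [(math.log(0.1), math.log(5.0))]  # log sigma_d
        if self.spec.family != "H":
            b += [(_logit(0.005), _logit(0.3))]  # logit lapse
        if self.spec.flexible_p_aff_by_N:
            b += [(_logit(0.2), _logit(0.8))] * len(self.n_set)
        if self.spec.flexible_sigmas:
            b += [(math.log(0.8), math.log(5.0))] * 2  # log sigma, log sigma_s
        return b


class ObserverChoiceModel:
    """One observer model bound to one subject's trials and choices.

    Parameters
    ----------
    model_id : catalogue ID or alias (e.g. ``"A1"``, ``"C_ac"``, ``"B6P"``).
    trials : sequence of Trial.
    responses : binary array, one response per trial (1 = "source present").
    R : arena radius assumed by the observer (park units).
    """

    def __init__(self, model_id: str, trials: Sequence, responses, R: float = 10.0):
        self.model_id, self.spec = resolve_model_id(model_id)
        self.trials = list(trials)
        self.responses = np.asarray(responses, dtype=int)
        if len(self.responses) != len(self.trials):
            raise ValueError("responses must align with trials")
        self.R = float(R)
        self.n_set = tuple(sorted({t.N for t in self.trials}))
        self.layout = _ParamLayout(self.spec, self.n_set)
        self._Ns = np.array([t.N for t in self.trials])
        self._d_cache: dict[tuple, np.ndarray] = {}
        self.fingerprint = _dataset_fingerprint(self.trials, self.responses)

    @classmethod
    def from_dataframe(
        cls, model_id: str, df: pd.DataFrame, response_col: str = "response",
        R: float = 10.0,
    ) -> "ObserverChoiceModel":
        """Build from a wide-format trial table that includes a response column."""
        from .task import frame_to_trials

        return cls(model_id, frame_to_trials(df), df[response_col].to_numpy(), R=R)

    # -- decision variables ------------------------------------------------
    def _belief_key(self, nat: dict) -> tuple:
        p = nat["p_aff_internal"]
        p_key = tuple(sorted(p.items())) if isinstance(p, dict) else p
        return (p_key, nat["sigma_internal"], nat["sigma_s_internal"])

    def decision_variables(self, nat: Optional[dict] = None) -> np.ndarray:
        nat = nat or {
            "p_aff_internal": 0.5,
            "sigma_internal": 2.0,
            "sigma_s_internal": 2.0,
        }
        key = self._belief_key(nat)
        if key not in self._d_cache:
            model = InternalModel(
                p_aff=nat["p_aff_internal"],
                sigma=nat["sigma_internal"],
                sigma_s=nat["sigma_s_internal"],
                R=self.R,
            )
            self._d_cache[key] = np.array(
                [decision_variable(self.spec, t, model)[0] for t in self.trials]
            )
        return self._d_cache[key]

    # -- objective ---------------------------------------------------------
    def _nll_from_natural(self, nat: dict) -> float:
        d = self.decision_variables(nat if self.layout.needs_inference else None)
        with_lapse = self.spec.family != "H"
        k = nat["k"]
        if isinstance(k, dict):
            kv = np.array([k[n] for n in self._Ns])
        else:
            kv = k
        from scipy.stats import norm

        core = norm.cdf((d - kv) / nat["sigma_d"])
        p = 0.5 * nat["lapse"] + (1 - nat["lapse"]) * core if with_lapse else core
        return _bernoulli_nll(p, self.responses)

    def nll(self, theta: np.ndarray) -> float:
        return self._nll_from_natural(self.layout.to_natural(theta))

    # -- fitting -----------------------------------------------------------
    def _tied_start(self, n_restarts: int, seed: int) -> Optional[np.ndarray]:
        """Fit the tied-criterion nested model and lift its solution, so a
        flexible-criterion fit can never fall below its nested counterpart."""
        if not self.spec.flexible_criteria_by_N:
            return None
        tied_spec = ObserverSpec(
            self.spec.family,
            self.spec.strategy,
            False,
            self.spec.flexible_p_aff_by_N,
            self.spec.flexible_sigmas,
        )
        tied = ObserverChoiceModel.__new__(ObserverChoiceModel)
        tied.model_id = self.model_id + "_tied"
        tied.spec = tied_spec
        tied.trials = self.trials
        tied.responses = self.responses
        tied.R = self.R
        tied.n_set = self.n_set
        tied.layout = _ParamLayout(tied_spec, self.n_set)
        tied._Ns = self._Ns
        tied._d_cache = self._d_cache  # share inference work
        tied.fingerprint = self.fingerprint
        res = tied.fit(n_restarts=max(3, n_restarts // 2), seed=seed + 1)
        theta_t = np.asarray(res._theta)
        k_tied = theta_t[0]
        return np.concatenate([[k_tied] * len(self.n_set), theta_t[1:]])

    def fit(
        self, n_restarts: int = 10, seed: int = 0, xatol: float = 1e-4,
        fatol: float = 1e-6, maxiter: Optional[int] = None,
    ) -> ObserverFitResults:
        """Multi-start Nelder-Mead maximum-likelihood fit."""
        bounds = np.array(self.layout.start_bounds())
        sampler = qmc.LatinHypercube(d=len(bounds), seed=seed)
        unit = sampler.random(n_restarts)
        starts = [bounds[:, 0] + u * (bounds[:, 1] - bounds[:, 0]) for u in unit]
        tied = self._tied_start(n_restarts, seed)
        if tied is not None:
            starts.append(tied)
        best = None
        n_ok = 0
        for x0 in starts:
            res = minimize(
                self.nll,
                x0,
                method="Nelder-Mead",
                options={
                    "xatol": xatol,
                    "fatol": fatol,
                    "maxiter": maxiter or 400 * len(bounds),
                },
            )
            n_ok += bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        nat = self.layout.to_natural(best.x)
        params = ObserverParams(
            k=nat["k"],
            sigma_d=nat["sigma_d"],
            lapse=nat["lapse"],
            p_aff_internal=nat["p_aff_internal"],
            sigma_internal=nat["sigma_internal"],
            sigma_s_internal=nat["sigma_s_internal"],
        )
        log_lik = -best.fun
        n_params = self.layout.n_free
        n = len(self.trials)
        out = ObserverFitResults(
            model_id=self.model_id,
            params=params,
            n_params=n_params,
            log_lik=log_lik,
            aic=2 * n_params - 2 * log_lik,
            bic=n_params * math.log(n) - 2 * log_lik,
            n_trials=n,
            n_restarts=len(starts),
            converged=n_ok > 0,
            seed=seed,
            dataset_fingerprint=self.fingerprint,
            param_names=tuple(self.layout.names),
            param_values=self.layout.natural_values(nat),
        )
        out._theta = best.x  # transformed-scale solution, for warm starts
        return out


def fit_model(
    model_id: str,
    trials: Sequence,
    responses,
    n_restarts: int = 10,
    seed: int = 0,
    R: float = 10.0,
) -> ObserverFitResults:
    """Convenience wrapper: build the model object and fit it."""
    return ObserverChoiceModel(model_id, trials, responses, R=R).fit(
        n_restarts=n_restarts, seed=seed
    )


def compare_models(
    fits: Sequence[ObserverFitResults], reference: Optional[str] = None
) -> pd.DataFrame:
    """Delta-AIC/BIC table across fitted models on one dataset.

    Deltas are reported relative to the reference model (default: the first
    fit) and to the best (lowest-AIC) model; rows sorted by AIC.
    """
    if not fits:
        raise ValueError("no fits to compare")
    prints = {f.dataset_fingerprint for f in fits}
    if len(prints) > 1:
        raise ValueError("fits come from different datasets")
    ref_id = reference or fits[0].model_id
    by_id = {f.model_id: f for f in fits}
    if ref_id not in by_id:
        raise KeyError(f"reference model {ref_id!r} not among the fits")
    ref = by_id[ref_id]
    best_aic = min(f.aic for f in fits)
    best_bic = min(f.bic for f in fits)
    rows = [
        {
            "model_id": f.model_id,
            "n_params": f.n_params,
            "log_lik": f.log_lik,
            "aic": f.aic,
            "bic": f.bic,
            "delta_aic_vs_ref": f.aic - ref.aic,
            "delta_bic_vs_ref": f.bic - ref.bic,
            "delta_aic_vs_best": f.aic - best_aic,
            "delta_bic_vs_best": f.bic - best_bic,
        }
        for f in fits
    ]
    return pd.DataFrame(rows).sort_values("aic", ignore_index=True)


# ---------------------------------------------------------------------------
# Recovery harnesses.
# ---------------------------------------------------------------------------


def _simulate_subject(
    generator_id: str,
    gen_params: ObserverParams,
    n_trials: int,
    task_params: TaskParams,
    rng: np.random.Generator,
):
    from .response import simulate_responses

    _, spec = resolve_model_id(generator_id)
    trials = sample_session(task_params, n_trials, rng)
    model = InternalModel.from_task(task_params)
    responses, d = simulate_responses(spec, gen_params, trials, rng, model=model)
    return trials, responses, d


def parameter_recovery(
    generator_id: str,
    gen_params: ObserverParams,
    n_reps: int = 10,
    n_trials: int = 2000,
    task_params: Optional[TaskParams] = None,
    seed: int = 0,
    n_restarts: int = 10,
) -> pd.DataFrame:
    """Simulate-and-refit: one row of generating vs recovered parameters per
    replicate dataset (the fitted model is the generating model)."""
    task_params = task_params or TaskParams()
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(ss.spawn(n_reps)):
        rng = np.random.default_rng(child)
        trials, responses, _ = _simulate_subject(
            generator_id, gen_params, n_trials, task_params, rng
        )
        fit = fit_model(
            generator_id, trials, responses,
            n_restarts=n_restarts, seed=seed + 1000 + rep, R=task_params.R,
        )
        row = {"rep": rep, "log_lik": fit.log_lik, "converged": fit.converged}
        for name, val in zip(fit.param_names, fit.param_values):
            row[f"fit_{name}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def model_recovery(
    generator_id: str,
    gen_params: ObserverParams,
    fitter_ids: Sequence[str],
    n_subjects: int = 10,
    n_trials: int = 1000,
    task_params: Optional[TaskParams] = None,
    seed: int = 0,
    n_restarts: int = 8,
) -> pd.DataFrame:
    """Simulate subjects from one model and fit several candidates to each;
    returns one row per (subject, fitted model) with AIC/BIC."""
    task_params = task_params or TaskParams()
    ss = np.random.SeedSequence(seed)
    rows = []
    for subj, child in enumerate(ss.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        trials, responses, _ = _simulate_subject(
            generator_id, gen_params, n_trials, task_params, rng
        )
        for fid in fitter_ids:
            fit = fit_model(
                fid, trials, responses,
                n_restarts=n_restarts, seed=seed + 7000 + subj, R=task_params.R,
            )
            rows.append(
                {
                    "subject": subj,
                    "generator": generator_id,
                    "fitted": fit.model_id,
                    "n_params": fit.n_params,
                    "log_lik": fit.log_lik,
                    "aic": fit.aic,
                    "bic": fit.bic,
                }
            )
    return pd.DataFrame(rows)
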