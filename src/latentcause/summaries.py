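"""Descriptive analyses of (simulated) choice behaviour.

Quantile-binned response curves against heuristic stimulus statistics,
response rate against set size split by true category (with the
false-alarm-versus-N slope), response rate against the number of affiliated
or unaffiliated points, fixed-range decision-variable histograms, and the
evaluation-count (reaction-time proxy) curve over decision-variable
quantiles. All outputs are plain arrays/DataFrames so tests and downstream
plotting assert on numbers, not images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .task import Trial

__all__ = [
    "BinnedCurve",
    "bin_by_quantile",
    "binned_response_curve",
    "response_rate_by_N",
    "fa_effect_of_N",
    "curve_vs_affiliation",
    "decision_variable_histograms",
    "rt_proxy_curve",
]


@dataclass
class BinnedCurve:
    """Per-bin response proportions with binomial standard errors."""

    bin_centers: np.ndarray
    means: np.ndarray
    sems: np.ndarray
    n_per_bin: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "mean": self.means,
                "sem": self.sems,
                "n": self.n_per_bin,
            }
        )


def bin_by_quantile(values, n_bins: int) -> np.ndarray:
    """Rank-based assignment into ``n_bins`` groups of equal size (+-1).

    Ties are broken by stable input order (mergesort), so the assignment is
    permutation-equivariant on tie-free data and deterministic otherwise.
    """
    values = np.asarray(values)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > len(values):
        raise ValueError("n_bins exceeds the number of values")
    order = np.argsort(values, kind="mergesort")
    assignment = np.empty(len(values), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        assignment[chunk] = b
    return assignment


def binned_response_curve(values, responses, n_bins: int = 10) -> BinnedCurve:
    """Quantile-binned P(respond present) along a stimulus statistic."""
    values = np.asarray(values, dtype=float)
    responses = np.asarray(responses, dtype=float)
    bins = bin_by_quantile(values, n_bins)
    centers, means, sems, counts = [], [], [], []
    for b in range(n_bins):
        mask = bins == b
        n = int(mask.sum())
        p = responses[mask].mean()
        centers.append(values[mask].mean())
        means.append(p)
        sems.append(np.sqrt(p * (1 - p) / n))
        counts.append(n)
    return BinnedCurve(
        np.array(centers), np.array(means), np.array(sems), np.array(counts)
    )


def response_rate_by_N(
    trials: Sequence[Trial], responses, C: Optional[int] = None
) -> pd.DataFrame:
    """P(respond present) per set size, optionally restricted to one true
    category."""
    responses = np.asarray(responses, dtype=float)
    Ns = np.array([t.N for t in trials])
    Cs = np.array([-1 if t.C is None else t.C for t in trials])
    rows = []
    for n in np.unique(Ns):
        mask = Ns == n
        if C is not None:
            mask &= Cs == C
        if mask.sum() == 0:
            continue
        p = responses[mask].mean()
        rows.append(
            {
                "N": int(n),
                "rate": p,
                "sem": np.sqrt(p * (1 - p) / mask.sum()),
                "n_trials": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def fa_effect_of_N(trials: Sequence[Trial], responses) -> float:
    """OLS slope of the false-alarm rate against set size.

    The false-alarm rate is P(respond present | C = 0); the slope (per point
    added) is the key signature separating observers that grow more or less
    permissive as the number of background points increases.
    """
    tab = response_rate_by_N(trials, responses, C=0)
    if len(tab) < 2:
        raise ValueError("need C = 0 trials at >= 2 distinct N")
    slope, _ = np.polyfit(tab["N"].to_numpy(float), tab["rate"].to_numpy(), 1)
    return float(slope)


def curve_vs_affiliation(
    trials: Sequence[Trial], responses
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """P(respond present) against the true number of affiliated and of
    unaffiliated points, over C = 1 trials (requires ground-truth z)."""
    responses = np.asarray(responses, dtype=float)
    mask = np.array([t.C == 1 for t in trials])
    if not mask.any():
        raise ValueError("no C = 1 trials")
    sel = [t for t, m in zip(trials, mask) if m]
    if any(t.z is None for t in sel):
        raise ValueError("ground-truth affiliation vectors are required")
    resp = responses[mask]
    n1 = np.array([t.n_affiliated for t in sel])
    n0 = np.array([t.N - t.n_affiliated for t in sel])

    def table(counts):
        rows = []
        for c in np.unique(counts):
            m = counts == c
            p = resp[m].mean()
            rows.append(
                {
                    "count": int(c),
                    "rate": p,
                    "sem": np.sqrt(p * (1 - p) / m.sum()),
                    "n_trials": int(m.sum()),
                }
            )
        return pd.DataFrame(rows)

    return table(n1), table(n0)


def decision_variable_histograms(
    d_by_model: dict[str, np.ndarray],
    trials: Sequence[Trial],
    n_bins: int = 35,
    d_range: tuple[float, float] = (-10.0, 25.0),
) -> pd.DataFrame:
    """Fixed-range equal-width histograms of d per (model, N, true C).

    Defaults to 35 bins on [-10, 25]. Returns a long-format table with one
    row per (model, N, C, bin).
    """
    edges = np.linspace(d_range[0], d_range[1], n_bins + 1)
    Ns = np.array([t.N for t in trials])
    Cs = np.array([-1 if t.C is None else t.C for t in trials])
    rows = []
    for model_id, d in d_by_model.items():
        d = np.asarray(d, dtype=float)
        for n in np.unique(Ns):
            for c in np.unique(Cs):
                mask = (Ns == n) & (Cs == c)
                if not mask.any():
                    continue
                counts, _ = np.histogram(d[mask], bins=edges)
                for b in range(n_bins):
                    rows.append(
                        {
                            "model": model_id,
                            "N": int(n),
                            "C": int(c),
                            "bin_left": edges[b],
                            "bin_right": edges[b + 1],
                            "count": int(counts[b]),
                        }
                    )
    return pd.DataFrame(rows)


def rt_proxy_curve(d_values, n_evaluations, n_bins: int = 10) -> pd.DataFrame:
    """Mean evaluation count (reaction-time proxy) per decision-variable
    quantile bin."""
    d_values = np.asarray(d_values, dtype=float)
    n_evaluations = np.asarray(n_evaluations, dtype=float)
    bins = bin_by_quantile(d_values, n_bins)
    rows = []
    for b in range(n_bins):
        mask = bins == b
        rows.append(
            {
                "bin": b,
                "d_center": d_values[mask].mean(),
                "mean_evaluations": n_evaluations[mask].mean(),
                "sem": n_evaluations[mask].std(ddof=1) / np.sqrt(mask.sum())
                if mask.sum() > 1
                else 0.0,
                "n_trials": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)
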