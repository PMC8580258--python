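"""Optional thin plotting layer over the summary tables.

Every figure is backed by the numeric outputs in :mod:`latentcause.summaries`;
these helpers only draw them. matplotlib is imported lazily so the core
package works without it.
"""

from __future__ import annotations

import numpy as np


def plot_binned_curve(curve, ax=None, label=None, **kwargs):
    """Errorbar plot of a BinnedCurve (response proportion per bin)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ax.errorbar(
        curve.bin_centers, curve.means, yerr=curve.sems, marker="o",
        label=label, **kwargs,
    )
    ax.set_ylim(-0.02, 1.02)
    ax.set_ylabel("P(respond present)")
    return ax


def plot_rate_by_N(tables, ax=None, labels=None):
    """Response rate vs set size for one or more rate tables
    (from :func:`latentcause.summaries.response_rate_by_N`)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    if not isinstance(tables, (list, tuple)):
        tables = [tables]
    labels = labels or [None] * len(tables)
    for tab, label in zip(tables, labels):
        ax.errorbar(tab["N"], tab["rate"], yerr=tab["sem"], marker="o", label=label)
    ax.set_xlabel("set size N")
    ax.set_ylabel("P(respond present)")
    ax.set_ylim(-0.02, 1.02)
    return ax


def plot_decision_variable_histograms(table, model, C, ax=None):
    """Overlay per-set-size histograms of the decision variable for one
    model and true category (long-format table from
    :func:`latentcause.summaries.decision_variable_histograms`)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    sub = table[(table["model"] == model) & (table["C"] == C)]
    for n, grp in sub.groupby("N"):
        centers = (grp["bin_left"] + grp["bin_right"]) / 2
        ax.step(centers, grp["count"], where="mid", label=f"N = {n}")
    ax.set_xlabel("decision variable d")
    ax.set_ylabel("trials")
    ax.legend()
    return ax
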