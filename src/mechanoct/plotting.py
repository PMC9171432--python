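"""Publication-style figures for the mechano-regulation readouts."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .mechstats import CCRMatrix, ConditionalProbabilityCurve, ROCResult

__all__ = ["plot_probability_curves", "plot_roc", "plot_ccr_heatmap"]

_EVENT_COLORS = {"formation": "#1b7837", "quiescence": "#878787", "resorption": "#b2182b"}


def plot_probability_curves(
    curve: ConditionalProbabilityCurve, ax: Optional[plt.Axes] = None
) -> plt.Axes:
    """Conditional probability of F/Q/R versus normalized effective strain."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x = curve.bin_centers
    ok = curve.occupied
    for name, p in (
        ("formation", curve.p_form),
        ("quiescence", curve.p_quiesc),
        ("resorption", curve.p_res),
    ):
        ax.plot(x[ok], p[ok], "-o", ms=3, color=_EVENT_COLORS[name], label=name)
    ax.set_xlabel("normalized effective strain (fraction of 99th percentile)")
    ax.set_ylabel("conditional probability")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    return ax


def plot_roc(roc: ROCResult, ax: Optional[plt.Axes] = None) -> plt.Axes:
    """ROC curve with its AUC; the diagonal marks no association."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot(roc.fpr, roc.tpr, color="#2166ac", label=f"AUC = {roc.auc:.3f}")
    ax.plot([0, 1], [0, 1], "--", color="0.6", lw=1)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"{roc.event_type} (n+ = {roc.n_pos}, n- = {roc.n_neg})")
    ax.legend(frameon=False, loc="lower right")
    return ax


def plot_ccr_heatmap(ccr: CCRMatrix, ax: Optional[plt.Axes] = None) -> plt.Axes:
    """Correct-classification rate over the (lower, upper) threshold grid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    extent = [ccr.grid[0], ccr.grid[-1], ccr.grid[0], ccr.grid[-1]]
    im = ax.imshow(
        100.0 * ccr.ccr.T, origin="lower", extent=extent, aspect="auto",
        cmap="viridis", vmin=100.0 / 3.0,
    )
    tl, th = ccr.argmax
    ax.plot([tl], [th], "r*", ms=10, label=f"max CCR {ccr.max_ccr_percent:.1f}%")
    ax.set_xlabel("lower threshold (resorption)")
    ax.set_ylabel("upper threshold (formation)")
    ax.legend(frameon=False, loc="upper left")
    plt.colorbar(im, ax=ax, label="CCR (%)")
    return ax
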