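"""Standard method-comparison figures: Bland–Altman, mountain, ROC, scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .methodstats import BlandAltmanResult, MountainPlotResult, PassingBablokResult, RocResult

__all__ = [
    "bland_altman_plot",
    "mountain_plot_figure",
    "roc_plot",
    "passing_bablok_plot",
]


def bland_altman_plot(result: BlandAltmanResult, ax=None, out: str | Path | None = None):
    """Differences vs pairwise means with the bias and 95% LOA lines."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.differences, s=14, alpha=0.7)
    ax.axhline(result.bias, color="red", ls="--", label=f"bias {result.bias:.3g}")
    for loa in (result.loa_low, result.loa_high):
        ax.axhline(loa, color="gray", ls="--")
    unit = "%" if result.mode == "percent" else ""
    ax.set_xlabel("mean of methods")
    ax.set_ylabel(f"difference ({result.direction}){unit}")
    ax.legend(frameon=False)
    if out:
        ax.figure.savefig(out, dpi=150, bbox_inches="tight")
    return ax


def mountain_plot_figure(result: MountainPlotResult, ax=None, out: str | Path | None = None):
    """Folded percentile curve; the peak marks the median difference."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.plot(result.differences, result.folded_percentiles, "-o", ms=3)
    ax.axvline(result.center, color="red", ls="--", label=f"center {result.center:.3g}")
    ax.axhline(5.0, color="red", ls=":", lw=0.8)
    ax.set_xlabel("difference between methods")
    ax.set_ylabel("folded percentile (%)")
    ax.set_ylim(0, 55)
    ax.legend(frameon=False)
    if out:
        ax.figure.savefig(out, dpi=150, bbox_inches="tight")
    return ax


def roc_plot(result: RocResult, ax=None, out: str | Path | None = None):
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(result.fpr, result.tpr, label=f"AUC {result.auc:.3f}")
    ax.plot([0, 1], [0, 1], color="gray", ls=":")
    ax.scatter([1 - result.specificity], [result.sensitivity], color="red", zorder=3,
               label=f"threshold {result.threshold:.3g}")
    ax.set_xlabel("1 − specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(frameon=False)
    if out:
        ax.figure.savefig(out, dpi=150, bbox_inches="tight")
    return ax


def passing_bablok_plot(x, y, result: PassingBablokResult, ax=None, out: str | Path | None = None):
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    x = np.asarray(x, float)
    ax.scatter(x, y, s=14, alpha=0.7)
    grid = np.linspace(x.min(), x.max(), 50)
    ax.plot(grid, result.intercept + result.slope * grid, color="black",
            label=f"y = {result.intercept:.3g} + {result.slope:.3g}·x")
    ax.plot(grid, grid, color="gray", lw=0.8, label="identity")
    ax.set_xlabel("comparator")
    ax.set_ylabel("device")
    ax.legend(frameon=False)
    if out:
        ax.figure.savefig(out, dpi=150, bbox_inches="tight")
    return ax
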