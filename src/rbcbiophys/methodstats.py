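"""Method-comparison and diagnostic statistics for device validation.

The suite a clinical-device study runs against a comparator instrument:

* Bland–Altman agreement: bias = mean difference, 95% limits of agreement
  (LOA) = bias ± 1.96·SD of the differences; absolute or percent differences.
* Passing–Bablok regression: the robust non-parametric slope = shifted median
  of all pairwise slopes, with the classical rank-based confidence intervals.
* ROC analysis: empirical curve, trapezoid AUC (equal to the Mann–Whitney
  statistic), Youden-optimal threshold, Clopper–Pearson CIs for sensitivity
  and specificity, DeLong CI for the AUC.
* Mountain plot: empirical percentile of each ranked difference, folded above
  50 (percentile → 100 − percentile), summarized by its center (median
  difference) and the observed 5th/95th percentile differences.

Conventions are explicit because comparator studies mix them: the difference
direction (device − comparator by default) and absolute-vs-percent mode are
parameters; the folded curve uses Hazen midpoint percentiles while the
reported 5th/95th points use nearest-rank so they are observed differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

__all__ = [
    "PairedMeasurements",
    "BlandAltmanResult",
    "PassingBablokResult",
    "RocResult",
    "MountainPlotResult",
    "MethodComparisonResult",
    "bland_altman",
    "passing_bablok",
    "roc_analysis",
    "mountain_plot",
    "compare_methods",
]


@dataclass
class PairedMeasurements:
    """Comparator (x) vs device (y) values for the same samples."""

    x: np.ndarray
    y: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")

    @property
    def n(self) -> int:
        return len(self.x)


def _as_pairs(pairs: PairedMeasurements | tuple | Sequence) -> PairedMeasurements:
    if isinstance(pairs, PairedMeasurements):
        return pairs
    x, y = pairs
    return PairedMeasurements(np.asarray(x), np.asarray(y))


# --------------------------------------------------------------------------
# Bland–Altman


@dataclass
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float  # bias − 1.96·sd
    loa_high: float  # bias + 1.96·sd
    mode: str
    direction: str
    differences: np.ndarray = field(repr=False)
    means: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "mode": self.mode,
            "direction": self.direction,
        }


def bland_altman(
    pairs: PairedMeasurements | tuple,
    mode: Literal["absolute", "percent"] = "absolute",
    direction: Literal["y-x", "x-y"] = "y-x",
) -> BlandAltmanResult:
    """Agreement analysis: bias, SD of differences and 95% LOAs.

    ``mode="percent"`` expresses each difference as a percentage of the
    pairwise mean (used for relative quantities like morphology parameters);
    ``mode="absolute"`` keeps raw units (used for counts).
    """
    p = _as_pairs(pairs)
    if p.n < 3:
        raise ValueError("Bland–Altman requires n ≥ 3 pairs")
    diffs = p.y - p.x if direction == "y-x" else p.x - p.y
    means = 0.5 * (p.x + p.y)
    if mode == "percent":
        if np.any(means == 0):
            raise ValueError("percent mode undefined when a pairwise mean is 0")
        diffs = 100.0 * diffs / means
    elif mode != "absolute":
        raise ValueError(f"unknown mode {mode!r}")
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        mode=mode,
        direction=direction,
        differences=diffs,
        means=means,
    )


# --------------------------------------------------------------------------
# Passing–Bablok


@dataclass
class PassingBablokResult:
    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_ci: tuple[float, float]
    n: int
    ci_level: float
    ci_method: str = "rank-based (classical Passing–Bablok)"

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "slope_ci": list(self.slope_ci),
            "intercept": self.intercept,
            "intercept_ci": list(self.intercept_ci),
            "n": self.n,
            "ci_level": self.ci_level,
            "ci_method": self.ci_method,
        }


def _pairwise_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """All pairwise slopes, handling ties per the classical procedure.

    Identical points (0/0) are omitted; vertical pairs (x tie, y differing)
    contribute ±∞ and participate in the ordering; slopes exactly −1 are
    excluded (they cannot distinguish the direction of disagreement).
    """
    n = len(x)
    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = dy / dx
    s[(dx == 0) & (dy == 0)] = np.nan  # identical points: undefined, omitted
    s = s[~np.isnan(s)]
    return s[s != -1.0]


def passing_bablok(
    pairs: PairedMeasurements | tuple, ci_level: float = 0.95
) -> PassingBablokResult:
    """Classical Passing–Bablok regression with rank-based CIs.

    Slope = median of the pairwise slopes shifted by K, the count of slopes
    below −1 (which makes the estimator invariant to swapping the methods);
    intercept = median(y − slope·x), with its CI evaluated at the slope CI
    bounds.
    """
    p = _as_pairs(pairs)
    if p.n < 10:
        raise ValueError("Passing–Bablok requires n ≥ 10 pairs")
    if np.all(p.x == p.x[0]):
        raise ValueError("x values must not all be equal")
    s = np.sort(_pairwise_slopes(p.x, p.y))
    n_s = len(s)
    if n_s == 0:
        raise ValueError("no valid pairwise slopes (insufficient distinct x)")
    k = int(np.sum(s < -1.0))

    def _shifted_median(arr: np.ndarray, shift: int) -> float:
        m = len(arr)
        if m % 2:
            return float(arr[(m + 1) // 2 + shift - 1])
        return 0.5 * float(arr[m // 2 + shift - 1] + arr[m // 2 + shift])

    slope = _shifted_median(s, k)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    n = p.n
    c = z * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(round((n_s - c) / 2.0))
    m2 = n_s - m1 + 1
    lo_idx = np.clip(m1 + k, 1, n_s) - 1
    hi_idx = np.clip(m2 + k, 1, n_s) - 1
    slope_ci = (float(s[lo_idx]), float(s[hi_idx]))
    intercept = float(np.median(p.y - slope * p.x))
    intercept_ci = (
        float(np.median(p.y - slope_ci[1] * p.x)),
        float(np.median(p.y - slope_ci[0] * p.x)),
    )
    return PassingBablokResult(
        slope=slope,
        slope_ci=slope_ci,
        intercept=intercept,
        intercept_ci=intercept_ci,
        n=n,
        ci_level=ci_level,
    )


# --------------------------------------------------------------------------
# ROC


def _clopper_pearson(k: int, n: int, ci_level: float) -> tuple[float, float]:
    alpha = 1.0 - ci_level
    lo = stats.beta.ppf(alpha / 2.0, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the empirical AUC via placement values."""
    m, n = len(pos), len(neg)
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)  # per-positive placement
    v01 = psi.mean(axis=0)  # per-negative placement
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


@dataclass
class RocResult:
    auc: float
    auc_ci: tuple[float, float]
    threshold: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    thresholds: np.ndarray = field(repr=False)
    ci_method: str = "DeLong (AUC), Clopper–Pearson (sens/spec)"

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            "ci_method": self.ci_method,
        }


def roc_analysis(
    scores: Sequence[float],
    labels: Sequence[int],
    ci_level: float = 0.95,
) -> RocResult:
    """Empirical ROC with a Youden-optimal operating threshold.

    AUC by the trapezoid rule (identical to the Mann–Whitney pair-count
    statistic); threshold maximizes Youden's J = sensitivity + specificity − 1
    with positives called at score ≥ threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    fpr, tpr, thresholds = _roc_curve(labels, scores)
    auc_val = float(_trapezoid_auc(fpr, tpr))
    j = tpr - fpr
    best = int(np.argmax(j))
    thr = float(thresholds[best])
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    tp = int(np.sum(pos >= thr))
    tn = int(np.sum(neg < thr))
    sens = tp / len(pos)
    spec = tn / len(neg)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    half = z * np.sqrt(_delong_variance(pos, neg))
    return RocResult(
        auc=auc_val,
        auc_ci=(max(0.0, auc_val - half), min(1.0, auc_val + half)),
        threshold=thr,
        sensitivity=sens,
        sensitivity_ci=_clopper_pearson(tp, len(pos), ci_level),
        specificity=spec,
        specificity_ci=_clopper_pearson(tn, len(neg), ci_level),
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
    )


# --------------------------------------------------------------------------
# Mountain plot


@dataclass
class MountainPlotResult:
    center: float  # median difference (the mountain peak)
    p5: float  # observed 5th-percentile difference (nearest rank)
    p95: float  # observed 95th-percentile difference (nearest rank)
    differences: np.ndarray = field(repr=False)  # sorted
    folded_percentiles: np.ndarray = field(repr=False)  # Hazen midpoint, folded

    def to_dict(self) -> dict:
        return {"center": self.center, "p5": self.p5, "p95": self.p95}


def mountain_plot(
    pairs: PairedMeasurements | tuple,
    direction: Literal["y-x", "x-y"] = "y-x",
) -> MountainPlotResult:
    """Folded empirical-percentile curve of the ranked differences.

    Each sorted difference gets the Hazen midpoint percentile 100·(i−0.5)/n;
    percentiles above 50 are folded to 100 − percentile, so the curve peaks at
    the median (the mountain center).  The reported 5th/95th percentiles use
    the nearest-rank convention (observed differences).
    """
    p = _as_pairs(pairs)
    if p.n < 3:
        raise ValueError("mountain plot requires n ≥ 3 pairs")
    diffs = np.sort((p.y - p.x) if direction == "y-x" else (p.x - p.y))
    n = len(diffs)
    pct = 100.0 * (np.arange(1, n + 1) - 0.5) / n
    folded = np.minimum(pct, 100.0 - pct)

    def _nearest_rank(q: float) -> float:
        idx = max(int(np.ceil(q / 100.0 * n)), 1) - 1
        return float(diffs[idx])

    return MountainPlotResult(
        center=float(np.median(diffs)),
        p5=_nearest_rank(5.0),
        p95=_nearest_rank(95.0),
        differences=diffs,
        folded_percentiles=folded,
    )


# --------------------------------------------------------------------------
# Aggregate


@dataclass
class MethodComparisonResult:
    """Bundle of every comparison the validation suite produces."""

    bland_altman: BlandAltmanResult | None = None
    passing_bablok: PassingBablokResult | None = None
    roc: RocResult | None = None
    mountain: MountainPlotResult | None = None

    def to_dict(self) -> dict:
        return {
            name: (getattr(self, name).to_dict() if getattr(self, name) else None)
            for name in ("bland_altman", "passing_bablok", "roc", "mountain")
        }

    def summary(self) -> str:
        lines = ["Method comparison"]
        if self.bland_altman:
            b = self.bland_altman
            lines.append(
                f"  Bland–Altman ({b.mode}): bias {b.bias:.4g}, "
                f"LOA [{b.loa_low:.4g}, {b.loa_high:.4g}]"
            )
        if self.passing_bablok:
            r = self.passing_bablok
            lines.append(
                f"  Passing–Bablok: slope {r.slope:.4f} "
                f"CI ({r.slope_ci[0]:.4f}, {r.slope_ci[1]:.4f}); "
                f"intercept {r.intercept:.4f} "
                f"CI ({r.intercept_ci[0]:.4f}, {r.intercept_ci[1]:.4f})"
            )
        if self.roc:
            r = self.roc
            lines.append(
                f"  ROC: AUC {r.auc:.4f} CI ({r.auc_ci[0]:.4f}, {r.auc_ci[1]:.4f}); "
                f"threshold {r.threshold:.4g}, sens {r.sensitivity:.2%}, "
                f"spec {r.specificity:.2%}"
            )
        if self.mountain:
            m = self.mountain
            lines.append(
                f"  Mountain: center {m.center:.4g}, p5 {m.p5:.4g}, p95 {m.p95:.4g}"
            )
        return "\n".join(lines)


def compare_methods(
    x: Sequence[float],
    y: Sequence[float],
    labels: Sequence[int] | None = None,
    ba_mode: Literal["absolute", "percent"] = "absolute",
    ci_level: float = 0.95,
) -> MethodComparisonResult:
    """Run the full suite on one paired dataset.

    ROC treats ``y`` as the score when binary ``labels`` are given;
    Passing–Bablok is skipped below its n ≥ 10 minimum.
    """
    p = PairedMeasurements(np.asarray(x), np.asarray(y))
    result = MethodComparisonResult()
    result.bland_altman = bland_altman(p, mode=ba_mode)
    if p.n >= 10 and not np.all(p.x == p.x[0]):
        result.passing_bablok = passing_bablok(p, ci_level=ci_level)
    result.mountain = mountain_plot(p)
    if labels is not None:
        result.roc = roc_analysis(np.asarray(y), labels, ci_level=ci_level)
    return result
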