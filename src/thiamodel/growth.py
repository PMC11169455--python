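"""Microbial growth-curve analysis: exponential-phase rate estimation and
group comparison.

OD600 series are natural-log transformed; the exponential phase is the
longest contiguous window whose log-linear fit reaches the R² threshold, and
the growth rate (h⁻¹) is the slope of ln(OD) vs time over that window.
Groups of replicate rates are compared by one-way ANOVA followed by Tukey's
HSD post-hoc test, with significance tiers at P < 0.05 (significant) and
P < 0.01 (very significant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "GrowthCurve",
    "GrowthRateEstimate",
    "ComparisonReport",
    "estimate_growth_rate",
    "compare_groups",
    "curves_from_table",
]


@dataclass
class GrowthCurve:
    """One OD600 time series (times in hours, strictly increasing, >= 6 points)."""

    times: np.ndarray
    od: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape or self.times.ndim != 1:
            raise ValueError("times and od must be 1-D arrays of equal length")
        if len(self.times) < 6:
            raise ValueError("a growth curve needs at least 6 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("OD values must be >= 0")


@dataclass
class GrowthRateEstimate:
    """Exponential-phase slope of ln(OD) vs time, with the window it came from.

    ``rate`` is None when no window of the requested length reaches the R²
    threshold ("no exponential phase") — a result, not an error.
    """

    rate: float | None
    window: tuple[float, float] | None
    r_squared: float | None
    n_points: int
    label: str = ""

    @property
    def has_exponential_phase(self) -> bool:
        return self.rate is not None


def _all_window_fits(t: np.ndarray, y: np.ndarray, length: int):
    """Vectorized OLS slope and R² for every contiguous window of *length*.

    Uses prefix sums, so the whole window scan is O(n²) instead of O(n³).
    """
    def rolling(x):
        c = np.concatenate(([0.0], np.cumsum(x)))
        return c[length:] - c[:-length]

    st, sy = rolling(t), rolling(y)
    stt, syy, sty = rolling(t * t), rolling(y * y), rolling(t * y)
    sxx = stt - st * st / length
    sxy = sty - st * sy / length
    syy_c = syy - sy * sy / length
    slope = np.divide(sxy, sxx, out=np.zeros_like(sxx), where=sxx > 0)
    # zero-variance (flat) windows carry no growth signal: R² := 0, not 1
    denom = sxx * syy_c
    r2 = np.divide(sxy * sxy, denom, out=np.zeros_like(sxy), where=denom > 0)
    return slope, r2


def estimate_growth_rate(
    curve: GrowthCurve,
    min_window_points: int = 4,
    r2_threshold: float = 0.95,
    window_points: int = 10,
) -> GrowthRateEstimate:
    """Estimate the exponential-phase growth rate (h⁻¹) of one OD series.

    A window of ``window_points`` consecutive readings slides along the
    ln-transformed series; the exponential phase is the window with the
    steepest ordinary-least-squares slope among those whose fit reaches
    ``r2_threshold`` with a positive slope (the "easy linear" rule: on a
    saturating curve, the steepest log-linear segment *is* the exponential
    phase, whereas flatness-based selection drifts into the deceleration or
    stationary phase).  Ties break toward the earlier window.  On a pure
    exponential every window has slope exactly r, so the estimate is exact
    regardless of sampling interval.

    When no window qualifies — a flat or noise-dominated series — the result
    reports no exponential phase (``rate`` is None) rather than raising.
    Zero-OD points cannot be log-transformed and delimit the searchable runs.
    """
    if min_window_points < 4:
        raise ValueError("min_window_points must be >= 4")
    if window_points < min_window_points:
        raise ValueError("window_points must be >= min_window_points")
    t_all, od_all = curve.times, curve.od
    usable = od_all > 0
    best: tuple[float, float, int, int] | None = None  # (slope, r2, -start, length)

    i = 0
    n = len(t_all)
    while i < n:
        if not usable[i]:
            i += 1
            continue
        j = i
        while j < n and usable[j]:
            j += 1
        m = j - i
        length = min(window_points, m)
        if length >= min_window_points:
            t_run, y_run = t_all[i:j], np.log(od_all[i:j])
            slopes, r2s = _all_window_fits(t_run, y_run, length)
            good = (r2s >= r2_threshold) & (slopes > 0)
            for start in np.flatnonzero(good):
                key = (float(slopes[start]), float(r2s[start]), -(i + int(start)))
                if best is None or key > best[:3]:
                    best = key + (length,)
        i = j

    if best is None:
        return GrowthRateEstimate(
            rate=None, window=None, r_squared=None, n_points=0, label=curve.label
        )
    slope, r2, neg_start, length = best
    abs_start = -neg_start
    window = (float(t_all[abs_start]), float(t_all[abs_start + length - 1]))
    return GrowthRateEstimate(
        rate=slope, window=window, r_squared=r2, n_points=length, label=curve.label
    )


@dataclass
class ComparisonReport:
    """One-way ANOVA + Tukey HSD over groups of replicate growth rates."""

    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, significant, very_significant
    group_means: dict[str, float]

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        sig = self.tukey[self.tukey["p_adj"] < alpha]
        return list(zip(sig["group1"], sig["group2"]))


def compare_groups(estimates: Mapping[str, Sequence[float]]) -> ComparisonReport:
    """Compare >= 2 groups of replicate rates (>= 2 rates each).

    Degenerate data (all groups identical, zero variance) is reported as
    p = 1 with an empty significance set rather than a numerical error.
    """
    labels = list(estimates)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(estimates[g], dtype=float) for g in labels]
    for g, arr in zip(labels, groups):
        if len(arr) < 2:
            raise ValueError(f"group {g!r} needs at least two replicate rates")
    means = {g: float(arr.mean()) for g, arr in zip(labels, groups)}

    flat = np.concatenate(groups)
    membership = np.repeat(labels, [len(g) for g in groups])
    if np.ptp(flat) == 0:  # identical everywhere: no variance to test
        pairs = [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
        tukey = pd.DataFrame(
            {
                "group1": [p[0] for p in pairs],
                "group2": [p[1] for p in pairs],
                "meandiff": 0.0,
                "p_adj": 1.0,
                "significant": False,
                "very_significant": False,
            }
        )
        return ComparisonReport(
            f_statistic=0.0, p_value=1.0, tukey=tukey, group_means=means
        )

    f_stat, p_value = stats.f_oneway(*groups)
    hsd = pairwise_tukeyhsd(flat, membership, alpha=0.05)
    tukey = pd.DataFrame(
        hsd.summary().data[1:], columns=[c for c in hsd.summary().data[0]]
    )[["group1", "group2", "meandiff", "p-adj"]].rename(columns={"p-adj": "p_adj"})
    tukey["p_adj"] = np.asarray(hsd.pvalues, dtype=float)
    tukey["meandiff"] = np.asarray(hsd.meandiffs, dtype=float)
    tukey["significant"] = tukey["p_adj"] < 0.05
    tukey["very_significant"] = tukey["p_adj"] < 0.01
    return ComparisonReport(
        f_statistic=float(f_stat), p_value=float(p_value), tukey=tukey, group_means=means
    )


def curves_from_table(frame: pd.DataFrame) -> list[GrowthCurve]:
    """Split a tidy (time_h, od600, label, replicate) table into curves."""
    required = {"time_h", "od600", "label", "replicate"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"growth table missing column(s) {sorted(missing)}")
    curves = []
    for (label, rep), sub in frame.groupby(["label", "replicate"], sort=True):
        sub = sub.sort_values("time_h")
        curves.append(
            GrowthCurve(
                times=sub["time_h"].to_numpy(float),
                od=sub["od600"].to_numpy(float),
                label=f"{label}/{rep}",
            )
        )
    return curves
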