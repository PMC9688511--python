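"""Group statistics over per-cell FLIM metrics, and colocalization.

The comparison procedure mirrors standard per-cell FLIM practice: trim
percentile outliers (default: strictly below the 1st and strictly above
the 99th percentile), record Shapiro-Wilk normality per group (reported,
never used to switch the test), then compare groups with the
unequal-variance (Welch) t-test, Bonferroni-adjusted when more than two
groups are compared. Colocalization of two channels within a mask is
quantified by the Pearson pixel correlation and the Manders M1
coefficient.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu

from .core import LabelMask, require_same_grid
from .errors import (
    ConstantChannelError,
    DegenerateDataError,
    TooFewObservationsError,
    UnsupportedSampleSizeError,
)

__all__ = [
    "GroupTable",
    "ColocResult",
    "trim_percentile_outliers",
    "shapiro_normality",
    "welch_ttest",
    "colocalization",
    "manders_m1",
    "summarize_groups",
]

TABLE_COLUMNS = ("group", "cell_label", "compartment", "metric", "value")


@dataclass
class GroupTable:
    """Long-format per-cell metric table feeding the statistics stage.

    One row per (group, cell, compartment, metric); duplicate keys are
    rejected so a cell cannot silently contribute twice.
    """

    data: pd.DataFrame
    groups: tuple = ()

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"GroupTable missing columns: {missing}")
        key = ["group", "cell_label", "compartment", "metric"]
        if self.data.duplicated(subset=key).any():
            raise ValueError("duplicate (group, cell, compartment, metric) rows")
        if not self.groups:
            self.groups = tuple(pd.unique(self.data["group"]))
        unknown = set(self.data["group"]) - set(self.groups)
        if unknown:
            raise ValueError(f"rows reference undeclared groups: {sorted(unknown)}")

    def values(self, group: str, metric: str, compartment: Optional[str] = None) -> np.ndarray:
        sel = (self.data["group"] == group) & (self.data["metric"] == metric)
        if compartment is not None:
            sel &= self.data["compartment"] == compartment
        return self.data.loc[sel, "value"].to_numpy(dtype=float)


@dataclass
class ColocResult:
    """Pixel colocalization of two channels within a mask."""

    pearson_r: float
    manders_m1: float
    n_pixels: int
    threshold_a: float
    threshold_b: float


def trim_percentile_outliers(
    values: Sequence[float],
    low: float = 1.0,
    high: float = 99.0,
) -> Tuple[np.ndarray, int]:
    """Drop values strictly below the ``low`` / strictly above the ``high``
    percentile (linear-interpolation definition); order is preserved.

    Returns ``(kept_values, n_removed)``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise TooFewObservationsError("need at least 3 values to trim outliers")
    lo, hi = np.percentile(arr, [low, high])
    keep = (arr >= lo) & (arr <= hi)
    return arr[keep], int((~keep).sum())


def shapiro_normality(values: Sequence[float]) -> Tuple[float, float]:
    """Shapiro-Wilk test of normality; returns ``(W, p)``.

    Supported for 3 <= n <= 5000. The result is recorded alongside group
    comparisons but never gates them.
    """
    arr = np.asarray(values, dtype=float)
    if not 3 <= arr.size <= 5000:
        raise UnsupportedSampleSizeError(
            f"Shapiro-Wilk supported for 3..5000 values, got {arr.size}"
        )
    if np.ptp(arr) == 0:
        raise DegenerateDataError("Shapiro-Wilk W undefined for a constant sample")
    res = stats.shapiro(arr)
    return float(res.statistic), float(res.pvalue)


def welch_ttest(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float, float]:
    """Unequal-variance two-sample t-test; returns ``(t, df, p)``.

    Degrees of freedom follow Welch–Satterthwaite. Two zero-variance
    samples with equal means return ``(0, nan, 1)`` by convention (with a
    warning) rather than an undefined statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise TooFewObservationsError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            warnings.warn("both samples constant and equal; p = 1 by convention",
                          stacklevel=2)
            return 0.0, float("nan"), 1.0
        raise DegenerateDataError("zero variance in both samples with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    se2a, se2b = va / a.size, vb / b.size
    df = (se2a + se2b) ** 2 / (
        se2a**2 / (a.size - 1) + se2b**2 / (b.size - 1)
    )
    return float(res.statistic), float(df), float(res.pvalue)


def manders_m1(
    chan_a: np.ndarray,
    chan_b: np.ndarray,
    mask: np.ndarray,
    threshold_b: Optional[float] = None,
) -> Tuple[float, float]:
    """Manders M1: fraction of channel-A intensity where B is above threshold.

    ``threshold_b`` defaults to Otsu within the mask. Returns
    ``(m1, threshold_b)``.
    """
    a, b, sel = _coloc_arrays(chan_a, chan_b, mask)
    if threshold_b is None:
        threshold_b = float(threshold_otsu(b))
    denom = a.sum()
    if denom <= 0:
        raise DegenerateDataError("channel A has no intensity within the mask")
    m1 = float(a[b > threshold_b].sum() / denom)
    return m1, float(threshold_b)


def _coloc_arrays(chan_a, chan_b, mask):
    chan_a = np.asarray(chan_a, dtype=float)
    chan_b = np.asarray(chan_b, dtype=float)
    require_same_grid(chan_a.shape, chan_b.shape)
    sel = mask.labels > 0 if isinstance(mask, LabelMask) else np.asarray(mask) > 0
    require_same_grid(chan_a.shape, sel.shape)
    if not sel.any():
        raise DegenerateDataError("mask selects no pixels")
    return chan_a[sel], chan_b[sel], sel


def colocalization(
    chan_a: np.ndarray,
    chan_b: np.ndarray,
    mask: np.ndarray,
    thresholds: Optional[Tuple[float, float]] = None,
) -> ColocResult:
    """Pearson correlation and Manders M1 of two channels within a mask.

    Thresholds default to per-channel Otsu inside the mask and are
    recorded in the result. A constant channel makes the Pearson
    coefficient undefined and raises :class:`ConstantChannelError`
    (:func:`manders_m1` remains available in that case).
    """
    a, b, sel = _coloc_arrays(chan_a, chan_b, mask)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ConstantChannelError(
            "Pearson correlation undefined: constant channel within mask"
        )
    if thresholds is None:
        thr_a = float(threshold_otsu(a))
        thr_b = float(threshold_otsu(b))
    else:
        thr_a, thr_b = (float(t) for t in thresholds)
    r = float(np.corrcoef(a, b)[0, 1])
    m1, _ = manders_m1(chan_a, chan_b, mask, threshold_b=thr_b)
    return ColocResult(
        pearson_r=r,
        manders_m1=m1,
        n_pixels=int(a.size),
        threshold_a=thr_a,
        threshold_b=thr_b,
    )


def summarize_groups(
    table: GroupTable,
    metric: str,
    compartment: Optional[str] = None,
    low: float = 1.0,
    high: float = 99.0,
    alpha: float = 0.05,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group summaries and pairwise Welch comparisons after trimming.

    Returns ``(summary, pairwise)`` DataFrames. The summary holds n
    (after trimming), trimmed count, mean, sd, median, quartiles and the
    Shapiro-Wilk (W, p) per group; the pairwise table holds t, df, p and
    — when more than two groups are present — the Bonferroni-adjusted p
    (raw p times the number of comparisons, capped at 1), with a
    significance flag at ``alpha``.
    """
    groups = [g for g in table.groups]
    if len(groups) < 2:
        raise TooFewObservationsError("need at least 2 groups to compare")
    kept: Dict[str, np.ndarray] = {}
    summary_rows = []
    for g in groups:
        vals = table.values(g, metric, compartment)
        if vals.size == 0:
            warnings.warn(f"group {g!r} has no values for metric {metric!r}; excluded",
                          stacklevel=2)
            continue
        trimmed, n_removed = trim_percentile_outliers(vals, low, high)
        if trimmed.size < 2:
            warnings.warn(f"group {g!r} emptied by trimming; excluded", stacklevel=2)
            continue
        try:
            w, p_norm = shapiro_normality(trimmed)
        except (DegenerateDataError, UnsupportedSampleSizeError):
            w, p_norm = float("nan"), float("nan")
        q1, med, q3 = np.percentile(trimmed, [25, 50, 75])
        summary_rows.append(
            {
                "group": g,
                "n": trimmed.size,
                "n_trimmed": n_removed,
                "mean": trimmed.mean(),
                "sd": trimmed.std(ddof=1),
                "median": med,
                "q1": q1,
                "q3": q3,
                "shapiro_w": w,
                "shapiro_p": p_norm,
            }
        )
        kept[g] = trimmed
    summary = pd.DataFrame(summary_rows)

    usable = [g for g in groups if g in kept]
    pairs = list(itertools.combinations(usable, 2))
    n_comparisons = len(pairs)
    bonferroni = len(usable) > 2
    pair_rows = []
    for ga, gb in pairs:
        t, df, p = welch_ttest(kept[ga], kept[gb])
        p_adj = min(p * n_comparisons, 1.0) if bonferroni else p
        pair_rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "t": t,
                "df": df,
                "p": p,
                "p_adjusted": p_adj,
                "significant": p_adj <= alpha,
            }
        )
    pairwise = pd.DataFrame(pair_rows)
    return summary, pairwise
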