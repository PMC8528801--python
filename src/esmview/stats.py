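"""Descriptive statistics feeding the visualizations.

Four computations drive every figure: Tukey five-number summaries (boxplots
with 1.5×IQR whisker fences), classical LOESS smoothing (local linear fits
with a tricube kernel over a nearest-neighbour fraction of the data),
polarity composites (per-prompt mean of the positive or negative slider
items), and missingness accounting.  Episode flagging thresholds the
smoothed negative composite with a robust (median/MAD) rule — a descriptive
stand-in for spotting relapse periods by eye in the timeline.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .schema import MISSING, ESMDataset, Polarity, Questionnaire

__all__ = [
    "DEFAULT_BANDWIDTH",
    "WHISKER_IQR_MULTIPLIER",
    "BoxplotSummary",
    "SmoothCurve",
    "MissingnessTable",
    "FlaggedWindow",
    "boxplot_summary",
    "order_items_by_median",
    "loess_smooth",
    "composite_series",
    "flag_episodes",
    "missingness_summary",
]

#: Default LOESS nearest-neighbour fraction used throughout the package.
DEFAULT_BANDWIDTH = 0.2

#: Tukey fence multiplier: whiskers reach the most extreme data point within
#: this many interquartile ranges of the hinges.
WHISKER_IQR_MULTIPLIER = 1.5


@dataclass(frozen=True)
class BoxplotSummary:
    """Five-number summary plus outliers for one item (0–100 scale units)."""

    item_code: str
    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...] = ()


@dataclass
class SmoothCurve:
    """A LOESS-fitted series with its evaluation grid and bandwidth."""

    item_code: str
    grid_times: np.ndarray  # datetime64 array
    fitted: np.ndarray
    bandwidth: float


@dataclass
class MissingnessTable:
    """Per-item missing fractions, per-day answered counts, and gap runs."""

    item_missing_fraction: dict[str, float]
    item_missing_count: dict[str, int]
    n_prompts: int
    answered_per_day: "pd.Series"
    gaps: list[tuple[dt.datetime, dt.datetime, int]]  # (start, end, n_prompts)


@dataclass(frozen=True)
class FlaggedWindow:
    """A maximal period in which the smoothed negative composite is elevated."""

    start: dt.date
    end: dt.date

    def overlaps(self, start: dt.date, end: dt.date) -> bool:
        return self.start <= end and start <= self.end


class InsufficientDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Boxplots
# ---------------------------------------------------------------------------

def boxplot_summary(values: Sequence[float], item_code: str = "") -> BoxplotSummary:
    """Tukey boxplot statistics for one item.

    Quartiles use linear interpolation between order statistics; whiskers are
    the most extreme *data points* within 1.5×IQR of the first/third quartile;
    anything beyond is an outlier.  Missing values (NaN / :data:`MISSING`)
    are dropped first.
    """
    arr = np.asarray(
        [v for v in values if v is not MISSING and not (isinstance(v, float) and np.isnan(v))],
        dtype=float,
    )
    if arr.size == 0:
        raise InsufficientDataError(f"no non-missing values for {item_code or 'item'}")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence = q1 - WHISKER_IQR_MULTIPLIER * iqr
    hi_fence = q3 + WHISKER_IQR_MULTIPLIER * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    outliers = arr[(arr < lo_fence) | (arr > hi_fence)]
    return BoxplotSummary(
        item_code=item_code,
        n=int(arr.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(sorted(float(v) for v in outliers)),
    )


def order_items_by_median(
    summaries: Sequence[BoxplotSummary],
    polarity_of: Optional[dict[str, str]] = None,
    ascending: bool = True,
) -> list[str]:
    """Item codes sorted by median within each polarity group.

    Groups are kept contiguous, in order of first appearance; ties break
    alphabetically by code (ascending).  With no ``polarity_of`` mapping all
    items form a single group.
    """
    if not summaries:
        raise ValueError("need at least one summary")
    group_of = polarity_of or {}
    groups: dict[str, list[BoxplotSummary]] = {}
    for s in summaries:
        groups.setdefault(group_of.get(s.item_code, "all"), []).append(s)
    out: list[str] = []
    for members in groups.values():
        members.sort(key=lambda s: (s.median if ascending else -s.median, s.item_code))
        out.extend(s.item_code for s in members)
    return out


# ---------------------------------------------------------------------------
# LOESS
# ---------------------------------------------------------------------------

def _as_days(times: np.ndarray | Sequence) -> np.ndarray:
    """Convert times to float days (datetimes measured from the first time)."""
    arr = np.asarray(times)
    if np.issubdtype(arr.dtype, np.datetime64):
        return (arr - arr[0]) / np.timedelta64(1, "D") if arr.size else arr.astype(float)
    if arr.dtype == object and arr.size and isinstance(arr.flat[0], dt.datetime):
        t0 = arr.flat[0]
        return np.array([(t - t0).total_seconds() / 86400.0 for t in arr])
    return arr.astype(float)


def loess_smooth(
    times: Sequence,
    values: Sequence[float],
    bandwidth: float = DEFAULT_BANDWIDTH,
    grid_times: Optional[Sequence] = None,
    item_code: str = "",
) -> SmoothCurve:
    """Classical LOESS: pointwise tricube-weighted local linear regression.

    At each grid point the ``ceil(bandwidth * n)`` nearest observations (by
    time distance, in days) are fit with degree-1 weighted least squares,
    weights ``(1 - (d/d_max)^3)^3``; the fitted value at the grid point is
    returned.  No robustness iterations.  Missing values are dropped before
    fitting; fewer than 3 remaining points is an error.  A window with zero
    time spread falls back to the weighted mean.
    """
    if not 0 < bandwidth <= 1:
        raise ValueError(f"bandwidth must be in (0, 1], got {bandwidth}")
    t_raw = np.asarray(times)
    v = np.asarray(values, dtype=float)
    if t_raw.shape[0] != v.shape[0]:
        raise ValueError("times and values must have equal length")
    if grid_times is None:
        grid_raw = t_raw
    else:
        grid_raw = np.asarray(grid_times)

    # shared origin so observation and grid days are commensurate
    joint = np.concatenate([t_raw, grid_raw]) if t_raw.size else grid_raw
    days_all = _as_days(joint)
    x_all, g_all = days_all[: t_raw.shape[0]], days_all[t_raw.shape[0]:]

    keep = ~np.isnan(v)
    x, y = x_all[keep], v[keep]
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"LOESS needs >= 3 non-missing points, got {n}")
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]

    k = int(np.ceil(bandwidth * n))
    k = max(k, 2)
    fitted = np.empty(g_all.size)
    for j, g in enumerate(g_all):
        d = np.abs(x - g)
        idx = np.argpartition(d, k - 1)[:k]
        xw, yw, dw = x[idx], y[idx], d[idx]
        dmax = dw.max()
        if dmax == 0:
            fitted[j] = yw.mean()
            continue
        w = (1 - (dw / dmax) ** 3) ** 3
        sw = w.sum()
        if sw <= 0 or np.ptp(xw) == 0:
            fitted[j] = np.average(yw, weights=w) if sw > 0 else yw.mean()
            continue
        xm = np.average(xw, weights=w)
        ym = np.average(yw, weights=w)
        sxx = np.sum(w * (xw - xm) ** 2)
        if sxx <= 0:
            fitted[j] = ym
            continue
        slope = np.sum(w * (xw - xm) * (yw - ym)) / sxx
        fitted[j] = ym + slope * (g - xm)

    return SmoothCurve(
        item_code=item_code,
        grid_times=grid_raw,
        fitted=fitted,
        bandwidth=bandwidth,
    )


# ---------------------------------------------------------------------------
# Composites & episodes
# ---------------------------------------------------------------------------

def composite_series(dataset: ESMDataset, polarity: Polarity) -> pd.Series:
    """Per-prompt mean of the available slider items of one polarity.

    NaN where a prompt has no available item of that polarity (e.g. fully
    unanswered prompts).  Indexed by scheduled time.
    """
    if polarity not in ("positive", "negative"):
        raise ValueError(f"polarity must be 'positive' or 'negative', got {polarity!r}")
    codes = dataset.questionnaire.slider_codes(polarity)
    if not codes:
        raise ValueError(f"questionnaire has no {polarity} slider items")
    frame = dataset.values_frame(codes)
    return frame.mean(axis=1, skipna=True)


def _robust_sd(values: np.ndarray) -> float:
    """1.4826 × median absolute deviation (consistent for a normal sd)."""
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def flag_episodes(
    dataset: ESMDataset,
    k_sd: float = 2.0,
    min_days: int = 7,
    bandwidth: float = DEFAULT_BANDWIDTH,
) -> list[FlaggedWindow]:
    """Flag sustained elevations of the smoothed negative composite.

    The negative composite is LOESS-smoothed, then maximal runs of grid
    points above ``median + k_sd * robust_sd`` (robust sd = 1.4826·MAD of the
    smoothed series) lasting at least ``min_days`` days are returned, sorted
    and non-overlapping.  Returns an empty list when there is too little data
    to smooth.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    if min_days < 1:
        raise ValueError("min_days must be >= 1")
    series = composite_series(dataset, "negative").dropna()
    if len(series) < 3:
        return []
    curve = loess_smooth(series.index.values, series.values, bandwidth=bandwidth)
    smoothed = curve.fitted
    threshold = float(np.median(smoothed)) + k_sd * _robust_sd(smoothed)
    above = smoothed > threshold

    windows: list[FlaggedWindow] = []
    times = pd.DatetimeIndex(curve.grid_times)
    i = 0
    while i < above.size:
        if above[i]:
            j = i
            while j + 1 < above.size and above[j + 1]:
                j += 1
            start, end = times[i].date(), times[j].date()
            if (end - start).days + 1 >= min_days:
                windows.append(FlaggedWindow(start, end))
            i = j + 1
        else:
            i += 1
    return windows


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------

def missingness_summary(dataset: ESMDataset) -> MissingnessTable:
    """Account for every unanswered item and prompt.

    Per item: the fraction of prompts at which its value is missing (for
    conditional items this includes prompts where the parent condition did
    not hold).  Per day: how many of the scheduled prompts were answered.
    Gaps: maximal runs of consecutive unanswered prompts.
    """
    n = len(dataset.records)
    codes = dataset.questionnaire.codes
    miss_count = {c: 0 for c in codes}
    for rec in dataset.records:
        for c in codes:
            if rec.get(c) is MISSING:
                miss_count[c] += 1
    frac = {c: (miss_count[c] / n if n else 0.0) for c in codes}

    per_day: dict[dt.date, int] = {}
    for rec in dataset.records:
        per_day.setdefault(rec.date, 0)
        if rec.answered:
            per_day[rec.date] += 1
    answered_per_day = pd.Series(per_day, dtype=int).sort_index()

    gaps: list[tuple[dt.datetime, dt.datetime, int]] = []
    run_start: Optional[dt.datetime] = None
    run_len = 0
    last_time: Optional[dt.datetime] = None
    for rec in dataset.records:
        if not rec.answered:
            if run_start is None:
                run_start = rec.scheduled_time
                run_len = 0
            run_len += 1
            last_time = rec.scheduled_time
        else:
            if run_start is not None:
                gaps.append((run_start, last_time, run_len))
                run_start = None
    if run_start is not None:
        gaps.append((run_start, last_time, run_len))

    return MissingnessTable(
        item_missing_fraction=frac,
        item_missing_count=miss_count,
        n_prompts=n,
        answered_per_day=answered_per_day,
        gaps=gaps,
    )
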