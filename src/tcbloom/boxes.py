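"""Box-averaged time series, gap-aware compositing, and bloom/cooling metrics.

A pixel belongs to a box when its centre lies inside the bounds (all edges
inclusive).  Spatial means are cos(latitude) area-weighted and ignore NaN
(cloud-masked) pixels; a fully masked time yields a missing value.  Two-day
composites pool valid pixel-days across the whole window rather than
averaging daily means, which is what makes them robust to cloud gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .fields import GeoGrid, ScalarField


@dataclass(frozen=True)
class BoxRegion:
    """Rectangular lat/lon region, degrees, edges inclusive."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def __post_init__(self):
        if not (self.lat_min < self.lat_max and self.lon_min < self.lon_max):
            raise ValueError("box bounds must satisfy min < max on both axes")


@dataclass
class BoxSeries:
    """Box statistic per time with per-time valid-pixel counts."""

    times: np.ndarray
    values: np.ndarray
    n_valid: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "value": self.values, "n_valid": self.n_valid}
        )


@dataclass
class BloomMetrics:
    peak_value: float
    peak_time: pd.Timestamp
    baseline: float
    fold_increase: float
    lag_days: float


def box_indexers(grid: GeoGrid, box: BoxRegion) -> tuple:
    """Index arrays of grid rows/columns whose centres fall inside the box."""
    ilat = np.where((grid.lats >= box.lat_min) & (grid.lats <= box.lat_max))[0]
    ilon = np.where((grid.lons >= box.lon_min) & (grid.lons <= box.lon_max))[0]
    if ilat.size == 0 or ilon.size == 0:
        raise ValueError("box does not overlap the grid")
    return ilat, ilon


def _box_subset(field: ScalarField, box: BoxRegion) -> tuple:
    ilat, ilon = box_indexers(field.grid, box)
    sub = field.values[..., ilat, :][..., :, ilon]
    w = np.cos(np.deg2rad(field.grid.lats[ilat]))[:, None]
    w = np.broadcast_to(w, sub.shape[-2:]).copy()
    return sub, w


def box_mean(field: ScalarField, box: BoxRegion) -> BoxSeries:
    """Per-time cos(phi)-weighted mean over unmasked pixels in the box."""
    if field.values.ndim != 3:
        raise ValueError("box_mean expects a (time, lat, lon) field")
    sub, w = _box_subset(field, box)
    valid = ~np.isnan(sub)
    n_valid = valid.sum(axis=(-2, -1))
    wsum = np.where(valid, w, 0.0).sum(axis=(-2, -1))
    vsum = np.where(valid, sub * w, 0.0).sum(axis=(-2, -1))
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(n_valid > 0, vsum / wsum, np.nan)
    times = field.times if field.times is not None else np.arange(len(vals))
    return BoxSeries(times=np.asarray(times), values=vals, n_valid=n_valid)


def two_day_composite(
    field: ScalarField,
    box: BoxRegion,
    window_days: int = 2,
    mode: str = "pooled",
    sliding: bool = False,
) -> BoxSeries:
    """Composite daily fields into multi-day windows anchored at the first time.

    ``pooled`` (default): one weighted mean over all valid pixel-days in the
    window.  ``daily_mean``: mean of the available daily box means.  Windows
    tile the record (non-overlapping) unless ``sliding`` is set.  A window
    with no valid pixel-day is missing.  Window values are stamped with the
    window's first time.
    """
    if mode not in ("pooled", "daily_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    if field.values.ndim != 3:
        raise ValueError("two_day_composite expects a (time, lat, lon) field")
    times = pd.DatetimeIndex(field.times) if field.times is not None else None
    if times is not None and len(times) > 1:
        steps = np.unique(np.diff(times.values))
        if not np.all(steps == np.timedelta64(1, "D")):
            raise ValueError("two_day_composite requires a daily cadence")
    sub, w = _box_subset(field, box)
    nt = sub.shape[0]
    starts = range(0, nt - window_days + 1, 1) if sliding else range(0, nt, window_days)

    daily = box_mean(field, box) if mode == "daily_mean" else None
    out_t, out_v, out_n = [], [], []
    for s in starts:
        sl = slice(s, min(s + window_days, nt))
        chunk = sub[sl]
        valid = ~np.isnan(chunk)
        n = int(valid.sum())
        if mode == "pooled":
            if n == 0:
                val = np.nan
            else:
                wchunk = np.broadcast_to(w, chunk.shape)
                val = np.sum(chunk[valid] * wchunk[valid]) / np.sum(wchunk[valid])
        else:
            dvals = daily.values[sl]
            val = np.nanmean(dvals) if np.any(~np.isnan(dvals)) else np.nan
        out_v.append(val)
        out_n.append(n)
        out_t.append(times[s] if times is not None else s)
    return BoxSeries(
        times=np.asarray(out_t), values=np.asarray(out_v), n_valid=np.asarray(out_n)
    )


def _split_series(series: BoxSeries, passage_time, baseline_window_days: float,
                  baseline_end=None):
    times = pd.DatetimeIndex(series.times)
    passage = pd.Timestamp(passage_time)
    vals = np.asarray(series.values, dtype=float)
    # Baseline window normally ends at passage; it can be pinned earlier
    # (e.g. at the cyclone's first box entry) to keep pre-storm values clean.
    end = passage if baseline_end is None else pd.Timestamp(baseline_end)
    pre = (times > end - pd.Timedelta(days=baseline_window_days)) & (times <= end)
    post = times > passage
    pre_vals = vals[pre]
    pre_vals = pre_vals[~np.isnan(pre_vals)]
    if pre_vals.size == 0:
        raise ValueError("no valid values in the baseline window")
    baseline = float(np.mean(pre_vals))
    return times, vals, post, baseline, passage


def bloom_metrics(
    chl: BoxSeries,
    tc_passage_time,
    baseline_window_days: float = 6.0,
    baseline_end=None,
) -> BloomMetrics:
    """Peak, fold increase over baseline, and lag after cyclone passage.

    Baseline is the mean of valid values in the window ending at passage
    (or at ``baseline_end`` when given); the peak is the post-passage
    maximum (ties broken to the earliest time); lag is peak time minus
    passage time in days.
    """
    times, vals, post, baseline, passage = _split_series(
        chl, tc_passage_time, baseline_window_days, baseline_end
    )
    if baseline <= 0:
        raise ValueError("baseline must be positive for a fold increase")
    post_vals = np.where(post, vals, np.nan)
    if np.all(np.isnan(post_vals)):
        raise ValueError("no valid values after passage")
    ipeak = int(np.nanargmax(post_vals))
    peak = float(post_vals[ipeak])
    peak_time = times[ipeak]
    lag = (peak_time - passage) / pd.Timedelta(days=1)
    return BloomMetrics(
        peak_value=peak,
        peak_time=peak_time,
        baseline=baseline,
        fold_increase=peak / baseline,
        lag_days=float(lag),
    )


def cooling_metrics(
    sst: BoxSeries,
    tc_passage_time,
    baseline_window_days: float = 6.0,
    recovery_margin: float = 0.5,
    baseline_end=None,
) -> tuple:
    """(max_drop degC, persistence days) of post-passage surface cooling.

    max_drop is baseline minus the post-passage minimum; persistence is the
    length of the longest contiguous post-passage run of valid samples
    colder than baseline - recovery_margin, in days (run sample count times
    the cadence).
    """
    times, vals, post, baseline, _ = _split_series(
        sst, tc_passage_time, baseline_window_days, baseline_end
    )
    post_vals = np.where(post, vals, np.nan)
    if np.all(np.isnan(post_vals)):
        raise ValueError("no valid values after passage")
    max_drop = baseline - float(np.nanmin(post_vals))

    if len(times) > 1:
        cadence = float(np.median(np.diff(times.values) / np.timedelta64(1, "D")))
    else:
        cadence = 1.0
    cold = post & ~np.isnan(vals) & (vals < baseline - recovery_margin)
    best = run = 0
    for flag in cold:
        run = run + 1 if flag else 0
        best = max(best, run)
    return max_drop, best * cadence
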