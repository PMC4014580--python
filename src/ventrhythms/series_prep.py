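"""Hourly-grid construction and time-series preparation.

The analysis runs on a fixed hourly grid spanning the continuous
recording window. Faunal counts arrive as per-frame counts, sensor
records as high-frequency (30-s) streams; both are reduced to
:class:`HourlySeries` objects — one value per hourly slot, with an
explicit missing mask — before any rhythm or association analysis.

No interpolation or gap-filling is ever performed: downstream
periodogram and correlation routines consume missing values natively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "HourlySeries",
    "RawSensorSeries",
    "build_grid",
    "hourly_average",
    "fe_cycle_reduce",
    "counts_to_density",
    "trend_test",
    "detrend",
    "subsample",
]

HOUR = pd.Timedelta(hours=1)


@dataclass
class HourlySeries:
    """One variable on an hourly UTC grid with explicit missingness.

    Parameters
    ----------
    timestamps : pandas.DatetimeIndex
        Strictly increasing hourly grid (UTC).
    values : numpy.ndarray of float
        One value per slot; ``NaN`` at missing slots.
    units : str
        Unit label, e.g. ``"ind/m2"``, ``"degC"``, ``"uM"``, ``"%"``.
    name : str
        Variable name (taxon or probe id).
    """

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    units: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values must have equal length")
        if len(self.timestamps) > 1:
            steps = np.unique(np.diff(self.timestamps.asi8))
            # regular grid; hourly for raw series, k-hourly after subsampling
            if steps.size != 1 or steps[0] <= 0 or steps[0] % HOUR.value != 0:
                raise ValueError("timestamps must be a regular whole-hour grid")

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, ``True`` where the slot has no observation."""
        return np.isnan(self.values)

    @property
    def n(self) -> int:
        """Series length (number of slots, missing included)."""
        return len(self.values)

    @property
    def n_observed(self) -> int:
        return int((~self.missing_mask).sum())

    def observed(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (slot indices, values) of the non-missing slots."""
        idx = np.flatnonzero(~self.missing_mask)
        return idx, self.values[idx]

    def with_values(self, values: np.ndarray, units: str | None = None) -> "HourlySeries":
        return replace(
            self, values=np.asarray(values, dtype=float),
            units=self.units if units is None else units,
        )

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.timestamps, name=self.name or None)


@dataclass
class RawSensorSeries:
    """Raw sensor records (irregular or 30-s cadence), one probe.

    Timestamps must be non-decreasing; values may be at any cadence.
    """

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    probe_id: str = ""

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values must have equal length")
        if len(self.timestamps) > 1 and (np.diff(self.timestamps.asi8) < 0).any():
            raise ValueError("sensor timestamps must be non-decreasing")


def build_grid(start, end) -> pd.DatetimeIndex:
    """Closed-interval hourly grid from ``start`` to ``end`` inclusive.

    Both bounds must fall on whole hours. The study window
    2011-10-07 08:00 → 2011-10-30 14:00 UTC yields 559 slots.
    """
    start = pd.Timestamp(start)
    end = pd.Timestamp(end)
    if start.tz is None:
        start = start.tz_localize("UTC")
    if end.tz is None:
        end = end.tz_localize("UTC")
    for t, label in ((start, "start"), (end, "end")):
        if t != t.floor("h"):
            raise ValueError(f"{label} bound {t} is not aligned on a whole hour")
    if start > end:
        raise ValueError("start must not be after end")
    return pd.date_range(start, end, freq="h")


def hourly_average(raw: RawSensorSeries, grid: pd.DatetimeIndex) -> HourlySeries:
    """Average raw sensor records into hourly slots.

    Each slot takes the arithmetic mean of all raw values with
    timestamp in ``[slot, slot + 1 h)`` (left-closed, right-open);
    slots with no record are missing. An empty input gives an
    all-missing series.
    """
    grid = pd.DatetimeIndex(grid)
    out = np.full(len(grid), np.nan)
    if len(raw.values) > 0:
        ts = raw.timestamps
        if ts.tz is None:
            ts = ts.tz_localize(grid.tz)
        pos = grid.searchsorted(ts, side="right") - 1
        in_window = (pos >= 0) & (ts < grid[-1] + HOUR)
        valid = in_window & ~np.isnan(raw.values)
        if valid.any():
            sums = np.bincount(pos[valid], weights=raw.values[valid], minlength=len(grid))
            counts = np.bincount(pos[valid], minlength=len(grid))
            covered = counts > 0
            out[covered] = sums[covered] / counts[covered]
    return HourlySeries(grid, out, name=raw.probe_id)


def fe_cycle_reduce(cycles: list, timestamps=None, probe_id: str = "Fe") -> RawSensorSeries:
    """Reduce per-timepoint iron measurement cycles to one value each.

    The in-situ chemical analyser runs several measurement cycles per
    recording time; only the last two are trusted and their mean is
    kept. Timepoints with fewer than two cycles are flagged missing
    with a warning.

    Parameters
    ----------
    cycles : list of sequences
        One sequence of cycle readings per timepoint.
    timestamps : optional sequence of timestamps, one per timepoint.
    """
    n = len(cycles)
    if timestamps is None:
        timestamps = pd.date_range("2000-01-01", periods=n, freq="D", tz="UTC")
    timestamps = pd.DatetimeIndex(timestamps)
    if len(timestamps) != n:
        raise ValueError("one timestamp per measurement timepoint required")
    vals = np.full(n, np.nan)
    for i, c in enumerate(cycles):
        c = np.asarray(c, dtype=float)
        if c.size < 2:
            logger.warning(
                "timepoint %s has %d measurement cycle(s); need >=2, flagged missing",
                timestamps[i], c.size,
            )
            continue
        vals[i] = c[-2:].mean()
    return RawSensorSeries(timestamps, vals, probe_id=probe_id)


def counts_to_density(counts: HourlySeries, area_m2: float) -> HourlySeries:
    """Convert per-frame counts to densities in individuals per m².

    ``area_m2`` is the filmed surface (the study bush covers ~0.0355 m²).
    Missing counts stay missing.
    """
    if area_m2 <= 0:
        raise ValueError("area_m2 must be positive")
    return counts.with_values(counts.values / area_m2, units="ind/m2")


def trend_test(s: HourlySeries, alpha: float = 0.05) -> dict:
    """OLS slope test for a linear trend against the slot index.

    Returns ``{"slope", "p_value", "stationary"}`` where the series is
    called stationary when the two-sided slope p-value is >= ``alpha``.
    Periodogram analysis requires (trend-) stationary input; a series
    failing this screen should be detrended first.
    """
    idx, y = s.observed()
    if len(y) < 3:
        raise ValueError("trend test needs at least 3 non-missing values")
    res = stats.linregress(idx.astype(float), y)
    pval = float(res.pvalue)
    if np.isnan(pval):  # zero-variance (constant) series: no trend
        pval = 1.0
    return {
        "slope": float(res.slope),
        "p_value": pval,
        "stationary": bool(pval >= alpha),
    }


def detrend(s: HourlySeries) -> HourlySeries:
    """Remove a linear trend by OLS on the slot index; keep residuals.

    Missing slots are untouched. Residuals have mean zero by
    construction.
    """
    idx, y = s.observed()
    if len(y) < 3:
        raise ValueError("detrend needs at least 3 non-missing values")
    x = idx.astype(float)
    slope, intercept = np.polyfit(x, y, 1)
    out = np.full(s.n, np.nan)
    out[idx] = y - (slope * x + intercept)
    return s.with_values(out)


def subsample(s: HourlySeries, every_k_hours: int, anchor: int = 0) -> HourlySeries:
    """Keep every k-th slot, i.e. slots with (index − anchor) % k == 0.

    Used to examine associations at coarser sampling frequencies
    (4-hourly, 6-hourly, 12-hourly). Timestamps are preserved; nothing
    is interpolated.
    """
    if every_k_hours < 1:
        raise ValueError("every_k_hours must be >= 1")
    keep = (np.arange(s.n) - anchor) % every_k_hours == 0
    return HourlySeries(s.timestamps[keep], s.values[keep], units=s.units, name=s.name)
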