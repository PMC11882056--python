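"""Percentile-based extreme events in daily MLD and CHL series.

The detector adapts the marine-heatwave scheme of windowed day-of-year
percentile climatologies to mixed-layer and chlorophyll series: for each
day-of-year, all daily samples within an 11-day window (+/- 5 days) across
all years are pooled; the pool's mean and its 90th (upper) and 10th (lower)
percentiles form the raw climatology and thresholds, which are then
smoothed with a centred 30-day circular moving mean along the day-of-year
axis.  An extreme event is a maximal run of consecutive days beyond a
threshold lasting at least a minimum duration (4 days for MLD, 3 for CHL);
runs separated by even a single sub-threshold day are not merged (no
gap-joining by default).

Compound events are temporal overlaps of sign-matched extremes — a deep-MLD
event with a high-CHL event, or shallow with low.  The CHL response metric
is the fraction of all extreme-MLD days on which the regional CHL
standardised anomaly is beyond +/-0.5 (strict inequality by default; the
inclusive variant is selectable).

Detection operates on regionally averaged daily series; leap days are
pooled into a 366th day-of-year slot alongside their calendar neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdClimatology",
    "ExtremeEvent",
    "CompoundEvent",
    "build_threshold_climatology",
    "detect_extremes",
    "chl_response_fraction",
    "detect_compound",
    "event_mean_map",
    "events_to_frame",
    "compounds_to_frame",
]

_DAYS = 365


def day_of_year_slot(index: pd.DatetimeIndex) -> np.ndarray:
    """Map dates to slots 1..365 on a fixed calendar; Feb 29 -> slot 366."""
    doy = index.dayofyear.to_numpy().copy()
    is_leap = index.is_leap_year
    after_feb = doy > 59  # after Feb 28 in a non-leap year
    leap_shift = is_leap & after_feb
    feb29 = is_leap & (doy == 60)
    doy[leap_shift] -= 1
    doy[feb29] = 366
    return doy


@dataclass
class ThresholdClimatology:
    """Smoothed day-of-year climatology with a percentile threshold."""

    mean: np.ndarray        # 366 slots (slot 366 = Feb 29)
    threshold: np.ndarray   # 366 slots
    percentile: float
    half_window: int = 5
    smooth_days: int = 30

    def __post_init__(self):
        if len(self.mean) != 366 or len(self.threshold) != 366:
            raise ValueError("climatology needs 366 day-of-year slots")

    def at(self, index: pd.DatetimeIndex) -> tuple[np.ndarray, np.ndarray]:
        slots = day_of_year_slot(index) - 1
        return self.mean[slots], self.threshold[slots]


@dataclass
class ExtremeEvent:
    variable: str
    polarity: str            # "high" (deep MLD / high CHL) or "low"
    start: pd.Timestamp
    end: pd.Timestamp
    duration_days: int
    max_exceedance: float    # max |value - threshold| during the event
    mean_exceedance: float

    @property
    def days(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="D")


@dataclass
class CompoundEvent:
    mld_event: ExtremeEvent
    chl_event: ExtremeEvent
    overlap_start: pd.Timestamp
    overlap_end: pd.Timestamp

    @property
    def klass(self) -> str:
        return "deep-high" if self.mld_event.polarity == "high" else "shallow-low"

    @property
    def days(self) -> pd.DatetimeIndex:
        return pd.date_range(self.overlap_start, self.overlap_end, freq="D")


def _circular_moving_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving mean on a circular axis (window offsets -w//2..)."""
    n = len(x)
    half_lo = window // 2
    kernel_idx = np.arange(-half_lo, window - half_lo)
    out = np.zeros(n)
    for k in kernel_idx:
        out += np.roll(x, -k)
    return out / window


def build_threshold_climatology(series: pd.Series, percentile: float,
                                half_window: int = 5,
                                smooth_days: int = 30) -> ThresholdClimatology:
    """Windowed day-of-year pooling, percentile, then circular smoothing.

    For each of the 365 regular slots, all samples (across years) whose slot
    lies within ``half_window`` circular days are pooled; the pool mean and
    the requested percentile (linear interpolation between order statistics)
    are then smoothed with a centred ``smooth_days`` circular moving mean.
    Slot 366 (Feb 29) inherits the average of its neighbours Feb 28/Mar 1.
    """
    idx = series.index
    if not isinstance(idx, pd.DatetimeIndex):
        raise TypeError("series must be indexed by dates")
    span_years = (idx[-1] - idx[0]).days / 365.25
    if span_years < 2.0:
        raise ValueError("threshold climatology needs >= 2 years of daily data")
    vals = np.asarray(series.values, dtype=float)
    slots = day_of_year_slot(idx)
    # Feb 29 samples participate in the pools around the Feb/Mar boundary
    eff = np.where(slots == 366, 59.5, slots.astype(float))
    finite = np.isfinite(vals)
    mean = np.empty(_DAYS)
    thr = np.empty(_DAYS)
    for d in range(1, _DAYS + 1):
        dist = np.abs(eff - d)
        dist = np.minimum(dist, _DAYS - dist)  # circular distance
        pool = vals[(dist <= half_window) & finite]
        if pool.size == 0:
            mean[d - 1] = np.nan
            thr[d - 1] = np.nan
            continue
        mean[d - 1] = pool.mean()
        thr[d - 1] = np.percentile(pool, percentile)
    mean_s = _circular_moving_mean(mean, smooth_days)
    thr_s = _circular_moving_mean(thr, smooth_days)
    mean366 = np.append(mean_s, (mean_s[58] + mean_s[59]) / 2.0)
    thr366 = np.append(thr_s, (thr_s[58] + thr_s[59]) / 2.0)
    return ThresholdClimatology(mean366, thr366, percentile,
                                half_window, smooth_days)


def detect_extremes(series: pd.Series, thresholds: ThresholdClimatology,
                    polarity: str, min_duration: int,
                    variable: str = "mld",
                    join_gap: int = 0) -> list[ExtremeEvent]:
    """Maximal runs of threshold exceedance lasting >= ``min_duration`` days.

    polarity "high": value > threshold (use a high-percentile climatology);
    polarity "low": value < threshold (low percentile).  Missing days break
    runs.  By default no merging across sub-threshold days; ``join_gap`` > 0
    merges runs separated by at most that many days (before the duration
    filter), for comparison with marine-heatwave-style gap bridging.
    """
    if polarity not in ("high", "low"):
        raise ValueError("polarity must be 'high' or 'low'")
    if polarity == "high" and thresholds.percentile < 50:
        raise ValueError("high-polarity detection given a low-percentile threshold")
    if polarity == "low" and thresholds.percentile > 50:
        raise ValueError("low-polarity detection given a high-percentile threshold")
    idx = series.index
    vals = np.asarray(series.values, dtype=float)
    _, thr = thresholds.at(idx)
    with np.errstate(invalid="ignore"):
        exceed = vals > thr if polarity == "high" else vals < thr
    exceed &= np.isfinite(vals)
    # maximal runs; contiguity in calendar time (a date gap breaks a run)
    runs: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    run_start = prev_date = None
    for date, hit in zip(idx, exceed):
        contiguous = prev_date is not None and (date - prev_date).days == 1
        if hit and run_start is not None and not contiguous:
            runs.append((run_start, prev_date))
            run_start = date
        elif hit and run_start is None:
            run_start = date
        elif not hit and run_start is not None:
            runs.append((run_start, prev_date))
            run_start = None
        prev_date = date
    if run_start is not None:
        runs.append((run_start, idx[-1]))
    if join_gap > 0:
        joined = []
        for start, end in runs:
            if joined and (start - joined[-1][1]).days - 1 <= join_gap:
                joined[-1] = (joined[-1][0], end)
            else:
                joined.append((start, end))
        runs = joined
    events: list[ExtremeEvent] = []
    for start, end in runs:
        duration = (end - start).days + 1
        if duration < min_duration:
            continue
        window = series.loc[start:end]
        _, w_thr = thresholds.at(window.index)
        exc = np.abs(window.values - w_thr)
        events.append(ExtremeEvent(variable, polarity, start, end, duration,
                                   float(np.nanmax(exc)), float(np.nanmean(exc))))
    return events


def chl_response_fraction(mld_events: list[ExtremeEvent],
                          chl_anom: pd.Series, threshold: float = 0.5,
                          inclusive: bool = False) -> tuple[float, int]:
    """Percent of extreme-MLD days with CHL anomaly beyond the signed threshold.

    Deep (high-polarity) events count days with anomaly > +threshold,
    shallow events days with anomaly < -threshold (>= / <= if inclusive).
    Returns (percentage, number of event days); raises if there are no
    event days.
    """
    day_sign: dict[pd.Timestamp, int] = {}
    for ev in mld_events:
        s = 1 if ev.polarity == "high" else -1
        for d in ev.days:
            day_sign[d] = s
    if not day_sign:
        raise ValueError("no extreme-MLD days: response fraction undefined")
    hits = 0
    for d, s in day_sign.items():
        v = chl_anom.get(d, np.nan)
        if not np.isfinite(v):
            continue
        sv = s * v
        if (sv >= threshold) if inclusive else (sv > threshold):
            hits += 1
    n = len(day_sign)
    return 100.0 * hits / n, n


def detect_compound(mld_events: list[ExtremeEvent],
                    chl_events: list[ExtremeEvent]) -> list[CompoundEvent]:
    """Sign-matched temporal overlaps: deep&high and shallow&low pairs."""
    out = []
    for me in mld_events:
        for ce in chl_events:
            if me.polarity != ce.polarity:
                continue
            start = max(me.start, ce.start)
            end = min(me.end, ce.end)
            if start <= end:
                out.append(CompoundEvent(me, ce, start, end))
    return out


def event_mean_map(anom, start: pd.Timestamp, end: pd.Timestamp):
    """Per-pixel mean of daily anomaly maps over [start, end], missing-aware.

    ``anom`` is a DailyGrid or CompositeGrid of standardised anomalies.
    """
    da = anom.data
    sel = da.sel(time=slice(start, end))
    if sel.sizes.get("time", 0) == 0:
        raise ValueError(
            f"event window {start}..{end} has no overlap with the grid time axis"
        )
    return sel.mean("time", skipna=True)


def events_to_frame(events: list[ExtremeEvent]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "variable": e.variable, "polarity": e.polarity,
            "start": e.start.date().isoformat(), "end": e.end.date().isoformat(),
            "duration_days": e.duration_days,
            "max_exceedance": e.max_exceedance,
            "mean_exceedance": e.mean_exceedance,
        } for e in events
    ], columns=["variable", "polarity", "start", "end", "duration_days",
                "max_exceedance", "mean_exceedance"])


def compounds_to_frame(compounds: list[CompoundEvent]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "class": c.klass,
            "mld_start": c.mld_event.start.date().isoformat(),
            "mld_end": c.mld_event.end.date().isoformat(),
            "chl_start": c.chl_event.start.date().isoformat(),
            "chl_end": c.chl_event.end.date().isoformat(),
            "overlap_start": c.overlap_start.date().isoformat(),
            "overlap_end": c.overlap_end.date().isoformat(),
        } for c in compounds
    ], columns=["class", "mld_start", "mld_end", "chl_start", "chl_end",
                "overlap_start", "overlap_end"])
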