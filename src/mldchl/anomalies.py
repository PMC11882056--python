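"""Standardised anomalies and their correlation structure.

A standardised anomaly removes the seasonal cycle and puts MLD (metres) and
CHL (log10 mg/m3) on one dimensionless scale::

    anom(t) = (X(t) - mean_month(t)) / std_month(t)

with the mean and standard deviation taken per pixel per calendar month
over the whole baseline (sample std, ddof=1, configurable).  A composite is
assigned to the calendar month of its window start date.

On these anomalies the module computes

* per-pixel Pearson correlation maps with pairwise-complete samples,
  a minimum-pair gate (default n >= 100 of the ~253 winter composites,
  i.e. >= 40% coverage) and two-sided p-values from
  t = r*sqrt(n-2)/sqrt(1-r^2),
* regional anomaly time series (spatial means with a >= 10% coverage gate),
* lagged correlations out to 10 composite lags (40 days), and
* per-winter-season (OND / JFM) correlation series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .compositing import CompositeGrid
from .seasonal import pearson_p_value

__all__ = [
    "MonthlyClimatology",
    "CorrelationMap",
    "monthly_climatology",
    "standardise",
    "correlation_map",
    "region_anomaly_series",
    "lagged_correlation",
    "seasonal_window_correlation",
]


@dataclass
class MonthlyClimatology:
    """Per-pixel, per-calendar-month mean, std and sample count."""

    mean: xr.DataArray   # (month, lat, lon)
    std: xr.DataArray
    count: xr.DataArray
    ddof: int = 1
    min_count: int = 2

    @property
    def defined(self) -> xr.DataArray:
        """Where an anomaly can be formed: enough samples and positive std."""
        return (self.count >= self.min_count) & (self.std > 0)


@dataclass
class CorrelationMap:
    """Per-pixel r, p and pair count with a minimum-n gate applied."""

    r: xr.DataArray
    p: xr.DataArray
    n: xr.DataArray
    min_pairs: int

    @property
    def significant(self) -> xr.DataArray:
        return (self.p < 0.05) & np.isfinite(self.r)


def _month_key(cg: CompositeGrid) -> xr.DataArray:
    return xr.DataArray(cg.start_dates.month, dims="time",
                        coords={"time": cg.data["time"]}, name="month")


def monthly_climatology(composites: CompositeGrid, ddof: int = 1,
                        min_count: int = 2) -> MonthlyClimatology:
    """Mean/std per pixel per calendar month over all years of composites."""
    key = _month_key(composites)
    g = composites.data.groupby(key)
    mean = g.mean("time", skipna=True)
    with warnings.catch_warnings():
        # pixel-months with fewer than ddof+1 samples give undefined std
        warnings.simplefilter("ignore", RuntimeWarning)
        std = g.std("time", ddof=ddof, skipna=True)
    count = g.count("time")
    return MonthlyClimatology(mean, std, count, ddof=ddof, min_count=min_count)


def standardise(composites: CompositeGrid, clim: MonthlyClimatology) -> CompositeGrid:
    """(X - monthly mean) / monthly std; undefined cells masked, never inf."""
    key = _month_key(composites)
    mean = clim.mean.sel(month=key)
    std = clim.std.sel(month=key)
    ok = clim.defined.sel(month=key)
    with np.errstate(invalid="ignore", divide="ignore"):
        anom = (composites.data - mean) / std
    anom = anom.where(ok)
    anom = anom.drop_vars("month")
    anom.name = f"{composites.name}_anom"
    anom.attrs = dict(composites.data.attrs)
    anom.attrs["units"] = "1"
    counts = composites.counts.where(~anom.isnull(), 0).astype(int)
    return CompositeGrid(anom, counts, composites.window_days, log_space=False)


# ---------------------------------------------------------------------------
# correlation maps
# ---------------------------------------------------------------------------

def correlation_map(anom_a: CompositeGrid | xr.DataArray,
                    anom_b: CompositeGrid | xr.DataArray,
                    min_pairs: int = 100) -> CorrelationMap:
    """Pairwise-complete per-pixel Pearson r with the n >= ``min_pairs`` gate.

    p = 2 * (1 - tcdf(|t|, n-2)) with t = r*sqrt(n-2)/sqrt(1-r^2).
    """
    da = anom_a.data if isinstance(anom_a, CompositeGrid) else anom_a
    db = anom_b.data if isinstance(anom_b, CompositeGrid) else anom_b
    if da.shape != db.shape or not np.array_equal(da["time"].values, db["time"].values):
        raise ValueError("correlation_map: grids are misaligned")
    a, b = da.values, db.values
    valid = ~np.isnan(a) & ~np.isnan(b)
    n = valid.sum(axis=0)
    a0 = np.where(valid, a, 0.0)
    b0 = np.where(valid, b, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sa, sb = a0.sum(0), b0.sum(0)
        saa = (a0 * a0).sum(0)
        sbb = (b0 * b0).sum(0)
        sab = (a0 * b0).sum(0)
        cov = sab - sa * sb / n
        var_a = saa - sa * sa / n
        var_b = sbb - sb * sb / n
        r = cov / np.sqrt(var_a * var_b)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1))
    gated = (n < min_pairs) | (var_a <= 0) | (var_b <= 0)
    r = np.where(gated, np.nan, r)
    p = np.where(gated, np.nan, p)
    coords = {"lat": da["lat"].values, "lon": da["lon"].values}
    dims = ("lat", "lon")
    return CorrelationMap(
        xr.DataArray(r, dims=dims, coords=coords, name="r"),
        xr.DataArray(p, dims=dims, coords=coords, name="p"),
        xr.DataArray(n, dims=dims, coords=coords, name="n"),
        min_pairs,
    )


# ---------------------------------------------------------------------------
# regional series
# ---------------------------------------------------------------------------

def region_anomaly_series(anom: CompositeGrid, region_mask: xr.DataArray,
                          min_coverage: float = 0.10) -> pd.Series:
    """Spatial mean anomaly over a region, gated on fractional coverage.

    Composites where fewer than ``min_coverage`` of the region's pixels have
    data are set missing.  Returns a Series indexed by window start date.
    """
    m = region_mask.values.astype(bool)
    n_region = int(m.sum())
    if n_region == 0:
        raise ValueError("region mask selects no pixels")
    vals = anom.data.values[:, m]
    present = ~np.isnan(vals)
    n_ok = present.sum(axis=1)
    sums = np.where(present, vals, 0.0).sum(axis=1)
    means = np.where(n_ok > 0, sums / np.maximum(n_ok, 1), np.nan)
    means[n_ok < min_coverage * n_region] = np.nan
    return pd.Series(means, index=anom.start_dates, name=anom.name)


def lagged_correlation(series_a: pd.Series, series_b: pd.Series,
                       max_lag: int = 10, min_overlap: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson r of b lagged behind a, lags 0..max_lag.

    Returns a DataFrame (lag, r, p, n); lags with fewer than ``min_overlap``
    complete pairs get NaN.  The maximising-|r| lag is in ``attrs['best_lag']``.
    """
    a = np.asarray(series_a.values, dtype=float)
    b = np.asarray(series_b.values, dtype=float)
    if len(a) != len(b):
        raise ValueError("series length mismatch")
    rows = []
    for lag in range(max_lag + 1):
        x = a[: len(a) - lag] if lag else a
        y = b[lag:]
        ok = np.isfinite(x) & np.isfinite(y)
        n = int(ok.sum())
        if n < min_overlap or np.allclose(x[ok], x[ok][0]) or np.allclose(y[ok], y[ok][0]):
            rows.append((lag, np.nan, np.nan, n))
            continue
        r = float(np.corrcoef(x[ok], y[ok])[0, 1])
        rows.append((lag, r, pearson_p_value(r, n), n))
    df = pd.DataFrame(rows, columns=["lag", "r", "p", "n"])
    if df["r"].notna().any():
        df.attrs["best_lag"] = int(df.loc[df["r"].abs().idxmax(), "lag"])
    return df


_SEASON_MONTHS = {"OND": (10, 11, 12), "JFM": (1, 2, 3),
                  "AMJ": (4, 5, 6), "JAS": (7, 8, 9)}


def seasonal_window_correlation(series_a: pd.Series, series_b: pd.Series,
                                window: str = "OND",
                                min_pairs: int = 3) -> pd.DataFrame:
    """One Pearson r per season-year over 3-month windows (e.g. OND, JFM).

    The season-year is the calendar year of the window's first month, so
    JFM 2008 means Jan-Mar 2008 and OND 2007 means Oct-Dec 2007.  Returns
    (season_year, r, p, n, significant).
    """
    if window not in _SEASON_MONTHS:
        raise ValueError(f"unknown 3-month window {window!r}")
    months = _SEASON_MONTHS[window]
    idx = series_a.index
    if not idx.equals(series_b.index):
        raise ValueError("series are not aligned")
    sel = idx.month.isin(months)
    rows = []
    for year, sub_idx in pd.Series(np.arange(len(idx))[sel],
                                   index=idx[sel]).groupby(idx[sel].year):
        x = series_a.iloc[sub_idx.values].values
        y = series_b.iloc[sub_idx.values].values
        ok = np.isfinite(x) & np.isfinite(y)
        n = int(ok.sum())
        if n < min_pairs or np.allclose(x[ok], x[ok][0]) or np.allclose(y[ok], y[ok][0]):
            rows.append((int(year), np.nan, np.nan, n, False))
            continue
        r = float(np.corrcoef(x[ok], y[ok])[0, 1])
        p = pearson_p_value(r, n)
        rows.append((int(year), r, p, n, p < 0.05))
    return pd.DataFrame(rows, columns=["season_year", "r", "p", "n", "significant"])
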