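"""Climatological annual cycles and seasonal MLD-CHL co-variability.

The annual-cycle analysis asks how the mixed layer and surface chlorophyll
move together over the mean year of a sub-region: 4-day climatological maps
are built pixel-wise across years, spatially averaged over the region
(CHL back-transformed from log space so the regional value is a geometric
mean), and compared through

* relative changes between consecutive composites, in percent,
* the fraction of composites where the two variables change with the same
  sign (co-variability),
* conditional mean responses (mean % change of each variable over the
  co-increasing and co-decreasing composites separately), and
* ordinary least-squares regression CHL = a * MLD + b per season with an
  F-test for the slope and R-squared.

Winter is October-March and summer April-September by default, matching the
basin's blooming calendar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .compositing import CompositeGrid, back_transform_mean

__all__ = [
    "SeasonalCycle",
    "RegressionFit",
    "climatological_cycle",
    "relative_change",
    "sign_agreement",
    "conditional_mean_response",
    "fit_seasonal_regression",
    "pearson_cycle_correlation",
    "WINTER_MONTHS",
    "SUMMER_MONTHS",
]

WINTER_MONTHS = (10, 11, 12, 1, 2, 3)
SUMMER_MONTHS = (4, 5, 6, 7, 8, 9)


@dataclass
class SeasonalCycle:
    """Regional climatological cycle at composite-of-year resolution."""

    variable: str
    region: str
    composite_doy: np.ndarray     # day-of-year of each composite start
    months: np.ndarray            # calendar month of each composite start
    mean: np.ndarray
    std: np.ndarray
    units: str = ""

    def __post_init__(self):
        if np.any(self.std[np.isfinite(self.std)] < 0):
            raise ValueError("cycle std must be >= 0")
        if not (len(self.composite_doy) == len(self.mean) == len(self.std)):
            raise ValueError("cycle arrays must share one length")

    def season_mask(self, months: tuple[int, ...]) -> np.ndarray:
        return np.isin(self.months, months)


@dataclass
class RegressionFit:
    """OLS fit CHL = a * MLD + b with F-test significance."""

    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    p_value: float
    n: int

    def __post_init__(self):
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError("R-squared outside [0,1]")
        if self.n < 3:
            raise ValueError("regression needs n >= 3")


def climatological_cycle(composites: CompositeGrid, region_mask: xr.DataArray,
                         variable: str, region: str,
                         back_transform: bool = False) -> SeasonalCycle:
    """Pixel-wise climatology across years, then regional spatial average.

    Composites are grouped by composite-of-year (month, day of the window
    start); each group is averaged per pixel across years, the resulting
    climatological map is averaged over the region mask, and — for log-space
    CHL — back-transformed to mg/m3 (a regional geometric mean).
    """
    starts = composites.start_dates
    w = composites.window_days
    # block-of-year index: day offset from Jan 1 over the window length;
    # comparable across years for a year-anchored composite calendar
    block = (starts.dayofyear.to_numpy() - 1) // w
    key = xr.DataArray(block, dims="time",
                       coords={"time": composites.data["time"]}, name="block")
    da = composites.data.where(region_mask)
    grouped = da.groupby(key)
    clim_map = grouped.mean("time", skipna=True)            # (block, lat, lon)
    mean = clim_map.mean(("lat", "lon"), skipna=True).values
    with warnings.catch_warnings():
        # pixel-blocks with a single year of data give undefined sample std
        warnings.simplefilter("ignore", RuntimeWarning)
        std = da.groupby(key).std("time", ddof=1, skipna=True) \
                .mean(("lat", "lon"), skipna=True).values
    blocks = np.asarray(sorted(set(block.tolist())))
    doy = blocks * w + 1
    ref = pd.Timestamp(2001, 1, 1)
    months = np.array([(ref + pd.Timedelta(days=int(d - 1))).month for d in doy])
    order = np.argsort(doy)
    units = str(composites.data.attrs.get("units", ""))
    mean, std = mean[order], std[order]
    if back_transform and composites.log_space:
        # delta-method-free choice: back-transform the mean; spread is kept
        # in log space and converted via the same map for display only
        upper = back_transform_mean(mean + std)
        mean = back_transform_mean(mean)
        std = upper - mean
        units = units.replace("log10(", "").rstrip(")")
    return SeasonalCycle(variable, region, doy[order], months[order],
                         mean, std, units)


# ---------------------------------------------------------------------------
# co-variability statistics
# ---------------------------------------------------------------------------

def relative_change(series: np.ndarray) -> np.ndarray:
    """Percent change between consecutive values: (x[t+1]-x[t])/x[t]*100."""
    x = np.asarray(series, dtype=float)
    denom = x[:-1]
    zero = np.isclose(denom, 0.0)
    if zero.any():
        raise ValueError(
            f"relative_change: zero denominator at index {int(np.argmax(zero))}"
        )
    return (x[1:] - x[:-1]) / denom * 100.0


def sign_agreement(delta_mld: np.ndarray, delta_chl: np.ndarray,
                   count_ties: bool = False) -> tuple[float, int]:
    """Percent of composites where the two changes share a sign.

    Exactly-zero changes count as non-agreement unless ``count_ties``;
    returns (percentage, agreeing count).
    """
    a = np.asarray(delta_mld, dtype=float)
    b = np.asarray(delta_chl, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    sa, sb = np.sign(a), np.sign(b)
    agree = (sa == sb) & ((sa != 0) | count_ties)
    n = int(agree.sum())
    return 100.0 * n / len(a), n


def conditional_mean_response(delta_mld: np.ndarray, delta_chl: np.ndarray) -> dict:
    """Mean % changes over co-increasing and co-decreasing composites.

    Returns ``{"increasing": (mean dMLD, mean dCHL) | None,
    "decreasing": ...}``; a class with no members is None (undefined),
    never zero.
    """
    a = np.asarray(delta_mld, dtype=float)
    b = np.asarray(delta_chl, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    out = {}
    for label, sel in (("increasing", (a > 0) & (b > 0)),
                       ("decreasing", (a < 0) & (b < 0))):
        out[label] = (float(a[sel].mean()), float(b[sel].mean())) if sel.any() else None
    return out


def fit_seasonal_regression(mld_cycle: np.ndarray, chl_cycle: np.ndarray,
                            season_mask: np.ndarray | None = None) -> RegressionFit:
    """OLS of CHL on MLD over a season's composites, with slope F-test."""
    x = np.asarray(mld_cycle, dtype=float)
    y = np.asarray(chl_cycle, dtype=float)
    if season_mask is not None:
        x, y = x[season_mask], y[season_mask]
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"regression needs >= 3 paired composites, got {n}")
    if np.allclose(x, x[0]):
        raise ValueError("singular fit: MLD has zero variance in this season")
    if np.allclose(y, y[0]):
        # flat response: slope exactly 0 and nothing explained
        return RegressionFit(0.0, float(y.mean()), 0.0, 0.0, 1.0, n)
    res = stats.linregress(x, y)
    r2 = float(res.rvalue ** 2)
    # slope F-test for simple regression: F = t^2 on (1, n-2) dof
    if r2 >= 1.0 - 1e-15:
        f, p = np.inf, 0.0
    else:
        f = r2 / (1.0 - r2) * (n - 2)
        p = float(stats.f.sf(f, 1, n - 2))
    return RegressionFit(float(res.slope), float(res.intercept),
                         min(r2, 1.0), float(f), p, n)


def pearson_cycle_correlation(mld_cycle: np.ndarray, chl_cycle: np.ndarray) -> tuple[float, float, int]:
    """Pearson r between the two cycles, p from the t-distribution formula."""
    x = np.asarray(mld_cycle, dtype=float)
    y = np.asarray(chl_cycle, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("correlation needs >= 3 pairs")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("undefined correlation: zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    p = pearson_p_value(r, n)
    return r, p, n


def pearson_p_value(r: float, n: int) -> float:
    """Two-sided p for Pearson r: t = r*sqrt(n-2)/sqrt(1-r^2), p = 2(1-F_t(|t|))."""
    if n < 3:
        return float("nan")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n - 2))
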