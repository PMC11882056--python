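"""Synthetic daily MLD / CHL / K_d(490) fields with known ground truth.

The generator emulates the statistical structure of the real inputs the
analysis expects — a winter-deep / summer-shallow mixed-layer cycle that
strengthens towards the north of the domain, lognormal chlorophyll whose
log10 concentration responds linearly (coefficient ``beta``, optionally
lagged) to the standardised MLD anomaly, AR(1) red noise in both variables,
satellite-like Bernoulli missingness varying by month and latitude band,
and injectable multi-day extremes with a returned ground-truth ledger.

It makes no claim to ocean physics: there is no advection, no eddies, no
spatially correlated cloud masks.  Its purpose is to give every downstream
stage a testbed where the right answer is known by construction.

Model, per pixel (y = latitude, t = day)::

    MLD(t,y,x)   = m(y) + a(y) * cos(2*pi*(doy - phase)/365.25) + e_m(t,y,x)
    z(t,y,x)     = e_m / sigma_m                     (standardised anomaly)
    log10 CHL    = log10(base(y)) + A_c(y) * cos(...) + beta * z(t-lag) + e_c
    CHL          = 10 ** (log10 CHL), then Bernoulli-masked

with e_m, e_c independent AR(1) processes started from their stationary
distributions (sigma_m, sigma_c are the stationary standard deviations).
The contemporaneous correlation between z and the CHL log-anomaly is
therefore analytically ``beta / sqrt(beta**2 + sigma_c**2)``, which the
tests exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

from .grids import DailyGrid

__all__ = [
    "SyntheticConfig",
    "Injection",
    "MissingnessRule",
    "ConfigError",
    "generate_fields",
    "inject_extremes",
    "analytic_lag0_correlation",
    "true_standardised_anomalies",
]


class ConfigError(ValueError):
    """An invalid synthetic-generator configuration field."""


@dataclass(frozen=True)
class Injection:
    """A multi-day extreme to force into one variable.

    amplitude is in units of the local climatological (noise) standard
    deviation; polarity +1 deepens MLD / raises CHL, -1 the opposite.
    The spatial footprint is a lat/lon box; None means the whole domain.
    """

    variable: str  # "mld" or "chl"
    polarity: int  # +1 or -1
    start: str  # ISO date
    duration_days: int
    amplitude: float
    lat_min: float | None = None
    lat_max: float | None = None
    lon_min: float | None = None
    lon_max: float | None = None

    def __post_init__(self):
        if self.variable not in ("mld", "chl"):
            raise ConfigError(f"injection variable must be mld|chl, got {self.variable!r}")
        if self.polarity not in (1, -1):
            raise ConfigError("injection polarity must be +1 or -1")
        if self.duration_days < 1:
            raise ConfigError("injection duration_days must be >= 1")

    @property
    def end(self) -> pd.Timestamp:
        return pd.Timestamp(self.start) + pd.Timedelta(days=self.duration_days - 1)


@dataclass(frozen=True)
class MissingnessRule:
    """Bernoulli missing probability for given months and a latitude band."""

    months: tuple[int, ...]
    lat_min: float
    lat_max: float
    p: float

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ConfigError(f"missing probability must be in [0,1], got {self.p}")


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic field generator (a pure function of this)."""

    # domain
    lat_min: float = 10.0
    lat_max: float = 28.0
    lon_min: float = 34.0
    lon_max: float = 42.0
    cell_deg: float = 0.1
    start: str = "2002-10-01"
    end: str = "2013-03-31"
    # MLD seasonal cycle endpoints, interpolated linearly in latitude
    mld_winter_max_south: float = 40.0   # m
    mld_winter_max_north: float = 90.0   # m
    mld_summer_min_south: float = 12.0   # m
    mld_summer_min_north: float = 15.0   # m
    mld_phase_doy: float = 25.0          # day-of-year of the winter maximum
    # CHL base level and seasonality (log10 space)
    chl_base_south: float = 0.45         # mg/m3, mesotrophic south
    chl_base_north: float = 0.12         # mg/m3, oligotrophic north
    chl_seasonal_amp_log10: float = 0.18  # winter-high amplitude, log10 units
    # MLD -> CHL coupling
    beta: float = 0.5                    # log10 CHL per std of MLD anomaly
    coupling_lag_days: int = 0
    # noise (shared AR(1) coefficient, per-variable innovation std)
    ar1_coef: float = 0.3
    mld_innov_std: float = 6.0           # m
    chl_innov_std: float = 0.08          # log10 units
    # multiplier on the CHL innovation std during winter (Oct-Mar) months;
    # < 1 suppresses winter noise so the coupled winter signal dominates
    chl_noise_winter_factor: float = 1.0
    # missingness: base probability plus ordered override rules
    missing_base: float = 0.25
    missing_rules: tuple[MissingnessRule, ...] = ()
    # extreme injections
    injections: tuple[Injection, ...] = ()
    # bathymetry: deep central basin flanked by shallow shelves
    basin_depth: float = 1200.0          # m
    shelf_depth: float = 120.0           # m
    shelf_lon_fraction: float = 0.15     # of the lon span, each side
    seed: int = 0

    def __post_init__(self):
        if self.cell_deg <= 0:
            raise ConfigError("cell_deg must be > 0")
        if pd.Timestamp(self.end) < pd.Timestamp(self.start):
            raise ConfigError("end date precedes start date")
        if not abs(self.ar1_coef) < 1:
            raise ConfigError("ar1_coef magnitude must be < 1")
        if not 0.0 <= self.missing_base <= 1.0:
            raise ConfigError("missing_base must be in [0,1]")
        if self.mld_innov_std < 0 or self.chl_innov_std < 0:
            raise ConfigError("innovation stds must be >= 0")
        for fld in ("mld_winter_max_south", "mld_winter_max_north",
                    "mld_summer_min_south", "mld_summer_min_north"):
            if getattr(self, fld) <= 0:
                raise ConfigError(f"{fld} must be > 0")
        if self.chl_base_south <= 0 or self.chl_base_north <= 0:
            raise ConfigError("chl base levels must be > 0")

    # -- derived axes ----------------------------------------------------
    @property
    def lat(self) -> np.ndarray:
        n = int(round((self.lat_max - self.lat_min) / self.cell_deg))
        return self.lat_min + self.cell_deg * (np.arange(max(n, 1)) + 0.5)

    @property
    def lon(self) -> np.ndarray:
        n = int(round((self.lon_max - self.lon_min) / self.cell_deg))
        return self.lon_min + self.cell_deg * (np.arange(max(n, 1)) + 0.5)

    @property
    def time(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="D")

    @property
    def mld_noise_std(self) -> float:
        """Stationary std of the AR(1) MLD noise, in metres."""
        return self.mld_innov_std / np.sqrt(1.0 - self.ar1_coef ** 2)

    @property
    def chl_noise_std(self) -> float:
        """Stationary std of the AR(1) log10-CHL noise."""
        return self.chl_innov_std / np.sqrt(1.0 - self.ar1_coef ** 2)


def analytic_lag0_correlation(cfg: SyntheticConfig) -> float:
    """Model-implied lag-0 correlation of standardised MLD vs CHL log-anomaly."""
    b, s = cfg.beta, cfg.chl_noise_std
    if b == 0 and s == 0:
        return float("nan")
    return b / np.hypot(b, s)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _ar1(rng: np.random.Generator, n_t: int, shape: tuple[int, ...],
         coef: float, innov_std: float,
         innov_scale: np.ndarray | None = None) -> np.ndarray:
    """AR(1) process along axis 0, started from the stationary distribution.

    ``innov_scale`` optionally modulates the innovation std per time step
    (e.g. to suppress noise seasonally).
    """
    out = np.empty((n_t, *shape))
    if innov_std == 0.0:
        out.fill(0.0)
        return out
    stat = innov_std / np.sqrt(1.0 - coef ** 2)
    s0 = stat if innov_scale is None else stat * innov_scale[0]
    out[0] = rng.normal(0.0, s0, shape)
    innov = rng.normal(0.0, innov_std, (n_t - 1, *shape))
    if innov_scale is not None:
        innov *= innov_scale[1:].reshape(-1, *([1] * len(shape)))
    for t in range(1, n_t):
        out[t] = coef * out[t - 1] + innov[t - 1]
    return out


def _lat_interp(cfg: SyntheticConfig, south: float, north: float) -> np.ndarray:
    frac = (cfg.lat - cfg.lat_min) / max(cfg.lat_max - cfg.lat_min, 1e-12)
    return south + (north - south) * frac


def _seasonal_cos(time: pd.DatetimeIndex, phase_doy: float) -> np.ndarray:
    doy = time.dayofyear.to_numpy(dtype=float)
    return np.cos(2.0 * np.pi * (doy - phase_doy) / 365.25)


def mld_climatology(cfg: SyntheticConfig) -> np.ndarray:
    """Deterministic MLD seasonal cycle, shape (time, lat)."""
    wmax = _lat_interp(cfg, cfg.mld_winter_max_south, cfg.mld_winter_max_north)
    smin = _lat_interp(cfg, cfg.mld_summer_min_south, cfg.mld_summer_min_north)
    mean, amp = (wmax + smin) / 2.0, (wmax - smin) / 2.0
    season = _seasonal_cos(cfg.time, cfg.mld_phase_doy)  # (T,)
    return mean[None, :] + amp[None, :] * season[:, None]


def _injection_field(cfg: SyntheticConfig, variable: str) -> np.ndarray:
    """Additive injection field in noise-std units, shape (T, Y, X)."""
    time, lat, lon = cfg.time, cfg.lat, cfg.lon
    out = np.zeros((len(time), len(lat), len(lon)))
    for inj in cfg.injections:
        if inj.variable != variable:
            continue
        t0 = pd.Timestamp(inj.start)
        t1 = inj.end
        if t0 < time[0] or t1 > time[-1]:
            raise ConfigError(
                f"injection window {t0.date()}..{t1.date()} outside "
                f"time span {time[0].date()}..{time[-1].date()}"
            )
        tsel = (time >= t0) & (time <= t1)
        ysel = np.ones(len(lat), bool)
        xsel = np.ones(len(lon), bool)
        if inj.lat_min is not None:
            ysel &= lat >= inj.lat_min
        if inj.lat_max is not None:
            ysel &= lat <= inj.lat_max
        if inj.lon_min is not None:
            xsel &= lon >= inj.lon_min
        if inj.lon_max is not None:
            xsel &= lon <= inj.lon_max
        out[np.ix_(tsel, ysel, xsel)] += inj.polarity * inj.amplitude
    return out


def _bathymetry(cfg: SyntheticConfig) -> xr.DataArray:
    lat, lon = cfg.lat, cfg.lon
    depth = np.full((len(lat), len(lon)), cfg.basin_depth)
    span = cfg.lon_max - cfg.lon_min
    shelf = cfg.shelf_lon_fraction * span
    is_shelf = (lon < cfg.lon_min + shelf) | (lon > cfg.lon_max - shelf)
    depth[:, is_shelf] = cfg.shelf_depth
    da = xr.DataArray(depth, dims=("lat", "lon"),
                      coords={"lat": lat, "lon": lon}, name="depth",
                      attrs={"units": "m", "positive": "down"})
    return da


def _missing_prob(cfg: SyntheticConfig) -> np.ndarray:
    """Per (time, lat) missing probability from base + rules."""
    time, lat = cfg.time, cfg.lat
    p = np.full((len(time), len(lat)), cfg.missing_base)
    months = time.month.to_numpy()
    for rule in cfg.missing_rules:
        tsel = np.isin(months, rule.months)
        ysel = (lat >= rule.lat_min) & (lat < rule.lat_max)
        p[np.ix_(tsel, ysel)] = rule.p
    return p


def generate_fields(cfg: SyntheticConfig) -> tuple[DailyGrid, DailyGrid, DailyGrid, xr.DataArray, pd.DataFrame]:
    """Generate (MLD, CHL, Kd490, bathymetry, injection ledger).

    MLD is gap-free and strictly positive; CHL is lognormal, coupled to the
    lagged standardised MLD anomaly, and masked by the missingness model;
    Kd490 follows a fixed monotone power law of CHL (a stand-in optical
    relationship, not a retrieval algorithm).  Identical configs (including
    the seed) give bit-identical outputs.
    """
    rng = np.random.default_rng(cfg.seed)
    time, lat, lon = cfg.time, cfg.lat, cfg.lon
    T, Y, X = len(time), len(lat), len(lon)

    # --- MLD ------------------------------------------------------------
    clim = mld_climatology(cfg)  # (T, Y)
    e_m = _ar1(rng, T, (Y, X), cfg.ar1_coef, cfg.mld_innov_std)
    e_m += _injection_field(cfg, "mld") * max(cfg.mld_noise_std, 1e-12)
    mld = clim[:, :, None] + e_m
    np.clip(mld, 1.0, None, out=mld)  # mixed layer cannot outcrop above 1 m

    # --- CHL ------------------------------------------------------------
    sigma_m = cfg.mld_noise_std
    z = e_m / sigma_m if sigma_m > 0 else np.zeros_like(e_m)
    if cfg.coupling_lag_days > 0:
        z_lag = np.empty_like(z)
        z_lag[cfg.coupling_lag_days:] = z[:T - cfg.coupling_lag_days]
        z_lag[:cfg.coupling_lag_days] = z[0]  # hold-first boundary
    else:
        z_lag = z
    base = _lat_interp(cfg, np.log10(cfg.chl_base_south), np.log10(cfg.chl_base_north))
    season = _seasonal_cos(time, cfg.mld_phase_doy)
    if cfg.chl_noise_winter_factor != 1.0:
        winter = time.month.isin((10, 11, 12, 1, 2, 3)).astype(float)
        scale = np.where(winter > 0, cfg.chl_noise_winter_factor, 1.0)
    else:
        scale = None
    e_c = _ar1(rng, T, (Y, X), cfg.ar1_coef, cfg.chl_innov_std, scale)
    e_c += _injection_field(cfg, "chl") * max(cfg.chl_noise_std, 1e-12)
    log_chl = (base[None, :, None]
               + cfg.chl_seasonal_amp_log10 * season[:, None, None]
               + cfg.beta * z_lag + e_c)
    chl_full = 10.0 ** log_chl

    # --- missingness ----------------------------------------------------
    p_miss = _missing_prob(cfg)  # (T, Y)
    u = rng.random((T, Y, X))
    chl = np.where(u < p_miss[:, :, None], np.nan, chl_full)

    # --- Kd490 (monotone stand-in optics; masked like CHL) --------------
    kd490 = 0.0166 + 0.072 * np.power(chl, 0.67)

    coords = {"time": time, "lat": lat, "lon": lon}
    dims = ("time", "lat", "lon")
    mld_g = DailyGrid(xr.DataArray(mld, dims=dims, coords=coords, name="mld",
                                   attrs={"units": "m"}))
    chl_g = DailyGrid(xr.DataArray(chl, dims=dims, coords=coords, name="chl",
                                   attrs={"units": "mg m-3"}))
    kd_g = DailyGrid(xr.DataArray(kd490, dims=dims, coords=coords,
                                  name="kd_490", attrs={"units": "m-1"}))
    ledger = injection_ledger(cfg.injections)
    return mld_g, chl_g, kd_g, _bathymetry(cfg), ledger


def true_standardised_anomalies(cfg: SyntheticConfig, mld: DailyGrid,
                                chl: DailyGrid) -> tuple[xr.DataArray, xr.DataArray]:
    """Ground-truth standardised anomalies via the generator's own scaling.

    Removes the generator's known deterministic seasonal cycle from each
    field and divides by the known stationary noise std (MLD in metres,
    CHL in log10 space).  This is the reference against which parameter
    recovery is judged: unlike an estimated monthly climatology it leaves
    no within-month seasonal residue in the anomalies.
    """
    clim = mld_climatology(cfg)  # (T, Y)
    z_mld = (mld.data - xr.DataArray(
        clim[:, :, None] * np.ones((1, 1, len(cfg.lon))),
        dims=("time", "lat", "lon"),
        coords={"time": cfg.time, "lat": cfg.lat, "lon": cfg.lon},
    )) / max(cfg.mld_noise_std, 1e-12)
    base = _lat_interp(cfg, np.log10(cfg.chl_base_south),
                       np.log10(cfg.chl_base_north))
    season = _seasonal_cos(cfg.time, cfg.mld_phase_doy)
    det = (base[None, :, None]
           + cfg.chl_seasonal_amp_log10 * season[:, None, None])
    with np.errstate(invalid="ignore"):
        log_chl = np.log10(chl.values)
    z_chl = xr.DataArray(
        (log_chl - det) / max(cfg.chl_noise_std, 1e-12),
        dims=("time", "lat", "lon"),
        coords={"time": cfg.time, "lat": cfg.lat, "lon": cfg.lon},
    )
    z_mld.name, z_chl.name = "mld_anom_true", "chl_anom_true"
    return z_mld, z_chl


def injection_ledger(injections) -> pd.DataFrame:
    rows = [
        {
            "event_id": i,
            "variable": inj.variable,
            "polarity": inj.polarity,
            "start_date": pd.Timestamp(inj.start).date().isoformat(),
            "end_date": inj.end.date().isoformat(),
            "amplitude": inj.amplitude,
        }
        for i, inj in enumerate(injections)
    ]
    return pd.DataFrame(rows, columns=["event_id", "variable", "polarity",
                                       "start_date", "end_date", "amplitude"])


# ---------------------------------------------------------------------------
# post-hoc injection into an existing grid
# ---------------------------------------------------------------------------

def _doy_anomaly_std(grid: DailyGrid) -> np.ndarray:
    """Per-pixel std of the field after removing its day-of-year mean.

    A cheap local "climatological std" for scaling post-hoc injections when
    the generating process is unknown.
    """
    da = grid.data
    doy = da["time"].dt.dayofyear
    clim = da.groupby(doy.rename("doy")).mean("time")
    anom = da.groupby(doy.rename("doy")) - clim
    sd = anom.std("time", ddof=1).values
    return np.where(np.isfinite(sd) & (sd > 0), sd, np.nanmean(sd[sd > 0]) if np.any(sd > 0) else 1.0)


def inject_extremes(grid: DailyGrid, injections: list[Injection],
                    clim_std: np.ndarray | None = None) -> tuple[DailyGrid, pd.DataFrame]:
    """Shift values inside each injection window/footprint and return a ledger.

    The shift is amplitude x (local climatological std) with the requested
    polarity; overlapping injections add.  ``clim_std`` (lat x lon) overrides
    the internally estimated day-of-year-anomaly std.
    """
    if not injections:
        return grid, injection_ledger([])
    time, lat, lon = grid.time, grid.lat, grid.lon
    for inj in injections:
        if pd.Timestamp(inj.start) < time[0] or inj.end > time[-1]:
            raise ValueError(
                f"injection window {inj.start}..{inj.end.date()} outside "
                f"grid time span"
            )
    if clim_std is None:
        clim_std = _doy_anomaly_std(grid)
    shift = np.zeros_like(grid.values)
    for inj in injections:
        tsel = (time >= pd.Timestamp(inj.start)) & (time <= inj.end)
        ysel = np.ones(len(lat), bool)
        xsel = np.ones(len(lon), bool)
        if inj.lat_min is not None:
            ysel &= lat >= inj.lat_min
        if inj.lat_max is not None:
            ysel &= lat <= inj.lat_max
        if inj.lon_min is not None:
            xsel &= lon >= inj.lon_min
        if inj.lon_max is not None:
            xsel &= lon <= inj.lon_max
        box = np.ix_(tsel, ysel, xsel)
        shift[box] += inj.polarity * inj.amplitude * clim_std[np.ix_(ysel, xsel)][None, :, :]
    return grid.copy_with(grid.values + shift), injection_ledger(injections)
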