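"""Gridded daily fields: data model, NetCDF I/O, regridding and region masks.

The package-wide container for a daily field is :class:`DailyGrid`, a thin
validated wrapper around an :class:`xarray.DataArray` with dims
``(time, lat, lon)``.  Missing values are NaN; the boolean ``mask`` property
is True where a value is present.  Coordinates are cell centres in decimal
degrees; the time axis is daily and strictly increasing.

Region masks combine a latitude band with an isobath criterion on a
bathymetry grid (depth in metres, positive down): a pixel belongs to a
region when its water depth is at least the isobath depth (default 250 m,
confining the analysis to the deep basin away from shallow banks) and its
latitude falls inside the band.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "DailyGrid",
    "RegionSpec",
    "DEFAULT_REGIONS",
    "FormatError",
    "read_grid",
    "write_grid",
    "regrid_linear",
    "make_region_mask",
    "read_regions",
    "write_regions",
]

#: NetCDF engine used everywhere (NetCDF3 classic; no compression, text-safe
#: toolchain-wise and supported by any CF reader).
NC_ENGINE = "scipy"

_POSITIVE_VARS = {"mld", "chl", "kd_490", "kd_par", "z_eu"}


class FormatError(ValueError):
    """A file or object does not satisfy the expected grid layout."""


def _check_monotonic(vals: np.ndarray, name: str) -> None:
    d = np.diff(vals)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise FormatError(f"{name} axis is not strictly monotonic")


@dataclass
class DailyGrid:
    """A daily gridded field with an explicit missing-value mask.

    Parameters
    ----------
    data:
        DataArray with dims ``(time, lat, lon)``; NaN marks missing pixels.
        ``data.name`` is the variable name and ``data.attrs['units']`` the
        units string.
    """

    data: xr.DataArray

    def __post_init__(self) -> None:
        da = self.data
        missing = [d for d in ("time", "lat", "lon") if d not in da.dims]
        if missing:
            raise FormatError(f"grid lacks dimension(s): {', '.join(missing)}")
        da = da.transpose("time", "lat", "lon")
        _check_monotonic(np.asarray(da["lat"].values, dtype=float), "lat")
        _check_monotonic(np.asarray(da["lon"].values, dtype=float), "lon")
        t = pd.DatetimeIndex(da["time"].values)
        if len(t) > 1 and not t.is_monotonic_increasing:
            raise FormatError("time axis is not increasing")
        vals = da.values
        if np.isinf(vals).any():
            raise FormatError("grid contains non-finite (inf) values")
        if (da.name or "") in _POSITIVE_VARS:
            with np.errstate(invalid="ignore"):
                bad = int(np.sum(vals <= 0))  # NaN compares False
            if bad:
                raise FormatError(
                    f"{da.name} must be strictly positive where present "
                    f"({bad} offending pixels)"
                )
        object.__setattr__(self, "data", da)

    # -- conveniences -----------------------------------------------------
    @property
    def name(self) -> str:
        return str(self.data.name)

    @property
    def units(self) -> str:
        return str(self.data.attrs.get("units", ""))

    @property
    def time(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data["time"].values)

    @property
    def lat(self) -> np.ndarray:
        return np.asarray(self.data["lat"].values, dtype=float)

    @property
    def lon(self) -> np.ndarray:
        return np.asarray(self.data["lon"].values, dtype=float)

    @property
    def values(self) -> np.ndarray:
        return self.data.values

    @property
    def mask(self) -> np.ndarray:
        """True where a value is present."""
        return ~np.isnan(self.data.values)

    def copy_with(self, values: np.ndarray) -> "DailyGrid":
        da = self.data.copy(data=np.asarray(values, dtype=float))
        return DailyGrid(da)


@dataclass
class RegionSpec:
    """A named latitude band intersected with the deep-basin isobath mask."""

    name: str
    lat_min: float
    lat_max: float
    isobath_depth: float = 250.0

    def __post_init__(self) -> None:
        if self.lat_max <= self.lat_min:
            raise ValueError(f"region {self.name}: lat_max must exceed lat_min")
        if self.isobath_depth <= 0:
            raise ValueError(f"region {self.name}: isobath depth must be > 0")


def default_regions(lat_min: float = 10.0, lat_max: float = 28.0,
                    isobath_depth: float = 250.0) -> list[RegionSpec]:
    """Five north-to-south latitude bands over the analysis domain.

    The canonical sub-region names (NRS, NCRS, SCRS-N, SCRS-S, SRS) follow
    the biological-oceanography literature on the basin; the boundary
    latitudes are approximate, non-authoritative defaults spread over the
    configured domain and should be overridden with a region file for any
    real-data use.
    """
    edges = np.linspace(lat_min, lat_max, 6)
    names = ["SRS", "SCRS-S", "SCRS-N", "NCRS", "NRS"]
    return [
        RegionSpec(name, float(lo), float(hi), isobath_depth)
        for name, lo, hi in zip(names, edges[:-1], edges[1:])
    ]


DEFAULT_REGIONS = default_regions()


# ---------------------------------------------------------------------------
# NetCDF I/O
# ---------------------------------------------------------------------------

def write_grid(grid: DailyGrid, path: str | os.PathLike) -> None:
    """Write a DailyGrid to CF-style NetCDF (classic format)."""
    ds = grid.data.to_dataset(name=grid.name or "field")
    ds[grid.name or "field"].attrs.setdefault("units", grid.units)
    ds.to_netcdf(path, engine=NC_ENGINE)


def read_grid(path: str | os.PathLike, variable: str) -> DailyGrid:
    """Read ``variable`` from a NetCDF file into a DailyGrid.

    ``_FillValue``/``missing_value`` sentinels are decoded to NaN by xarray.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with xr.open_dataset(path, engine=NC_ENGINE) as ds:
        if variable not in ds:
            raise FormatError(
                f"variable {variable!r} absent from {path} "
                f"(has: {', '.join(ds.data_vars)})"
            )
        da = ds[variable].load()
    return DailyGrid(da)


def write_bathymetry(depth: xr.DataArray, path: str | os.PathLike) -> None:
    depth = depth.rename("depth")
    depth.attrs.setdefault("units", "m")
    depth.attrs.setdefault("positive", "down")
    depth.to_dataset().to_netcdf(path, engine=NC_ENGINE)


def read_bathymetry(path: str | os.PathLike) -> xr.DataArray:
    with xr.open_dataset(path, engine=NC_ENGINE) as ds:
        if "depth" not in ds:
            raise FormatError(f"bathymetry file {path} lacks variable 'depth'")
        return ds["depth"].load()


def write_regions(regions: list[RegionSpec], path: str | os.PathLike) -> None:
    """Plain-text region file: one `name lat_min lat_max` per line."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.name} {r.lat_min:g} {r.lat_max:g}\n")


def read_regions(path: str | os.PathLike,
                 isobath_depth: float = 250.0) -> list[RegionSpec]:
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"bad region line: {line!r}")
            regions.append(RegionSpec(parts[0], float(parts[1]),
                                      float(parts[2]), isobath_depth))
    return regions


# ---------------------------------------------------------------------------
# Regridding
# ---------------------------------------------------------------------------

def regrid_linear(source: DailyGrid, target_lat: np.ndarray,
                  target_lon: np.ndarray) -> DailyGrid:
    """Bilinear interpolation of a gap-free grid onto target lat/lon axes.

    Intended for interpolating the (gap-free) model MLD onto the satellite
    CHL grid.  Targets outside the source's convex hull raise — no silent
    extrapolation.
    """
    target_lat = np.asarray(target_lat, dtype=float)
    target_lon = np.asarray(target_lon, dtype=float)
    src_lat, src_lon = source.lat, source.lon
    for tgt, src, name in ((target_lat, src_lat, "lat"),
                           (target_lon, src_lon, "lon")):
        lo, hi = min(src[0], src[-1]), max(src[0], src[-1])
        if tgt.min() < lo - 1e-12 or tgt.max() > hi + 1e-12:
            raise ValueError(
                f"target {name} axis [{tgt.min():g}, {tgt.max():g}] extends "
                f"outside source hull [{lo:g}, {hi:g}]"
            )
    out = source.data.interp(lat=target_lat, lon=target_lon, method="linear")
    out.name = source.name
    out.attrs.update(source.data.attrs)
    return DailyGrid(out)


# ---------------------------------------------------------------------------
# Region masking
# ---------------------------------------------------------------------------

def make_region_mask(bathymetry: xr.DataArray, region: RegionSpec) -> xr.DataArray:
    """Boolean mask: depth >= isobath depth AND latitude inside the band.

    Depth convention is metres positive down; an all-negative bathymetry
    indicates the opposite convention and is rejected.
    """
    depth = np.asarray(bathymetry.values, dtype=float)
    if np.all(depth[np.isfinite(depth)] < 0):
        raise ValueError(
            "bathymetry depths are all negative; expected positive-down metres"
        )
    lat = bathymetry["lat"]
    mask = (bathymetry >= region.isobath_depth) & \
           (lat >= region.lat_min) & (lat < region.lat_max)
    mask.name = f"mask_{region.name}"
    return mask


def isobath_mask(bathymetry: xr.DataArray, isobath_depth: float = 250.0) -> xr.DataArray:
    """Deep-basin mask alone (no latitude band)."""
    whole = RegionSpec("basin", -90.0, 90.0, isobath_depth)
    return make_region_mask(bathymetry, whole)
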