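import numpy as np
import pandas as pd
import pytest
import xarray as xr

from mldchl.grids import DailyGrid
from mldchl.synthetic import SyntheticConfig


def make_grid(values, start="2003-01-01", lat=None, lon=None, name="mld",
              units="m"):
    """Small DailyGrid from a (time, lat, lon) array."""
    values = np.asarray(values, dtype=float)
    t, y, x = values.shape
    time = pd.date_range(start, periods=t, freq="D")
    lat = np.arange(y, dtype=float) + 10.0 if lat is None else np.asarray(lat)
    lon = np.arange(x, dtype=float) + 35.0 if lon is None else np.asarray(lon)
    da = xr.DataArray(values, dims=("time", "lat", "lon"),
                      coords={"time": time, "lat": lat, "lon": lon},
                      name=name, attrs={"units": units})
    return DailyGrid(da)


@pytest.fixture
def tiny_config():
    """Single-pixel, three-year generator config with modest noise."""
    return SyntheticConfig(lat_min=20.0, lat_max=20.5, lon_min=35.0,
                           lon_max=35.5, cell_deg=0.5,
                           start="2003-01-01", end="2005-12-31",
                           missing_base=0.0, seed=7)


@pytest.fixture
def small_domain_config():
    """A 6x4-pixel, three-year config with satellite-like missingness."""
    return SyntheticConfig(lat_min=14.0, lat_max=26.0, lon_min=34.0,
                           lon_max=42.0, cell_deg=2.0,
                           start="2003-01-01", end="2005-12-31",
                           missing_base=0.2, seed=11)
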