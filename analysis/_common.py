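"""Shared paths and loaders for the numbered analysis drivers.

The demo dataset lives under scratch/demo (daily NetCDF fields, ~6 winters
at 0.5 degree resolution); derived tables go to results/.  Run the drivers
in order, starting with 01_simulate.py.
"""

from pathlib import Path

from mldchl.grids import (default_regions, make_region_mask, read_bathymetry,
                          read_grid)
from mldchl.synthetic import Injection, SyntheticConfig

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "demo"
RESULTS = ROOT / "results"

#: ground-truth extremes injected into the demo record (a deep-MLD / high-CHL
#: pair in Dec 2005 and a shallow / low pair in Feb 2007)
DEMO_INJECTIONS = (
    Injection("mld", 1, "2005-12-05", 7, 3.0),
    Injection("chl", 1, "2005-12-07", 5, 3.0),
    Injection("mld", -1, "2007-02-08", 6, 3.0),
    Injection("chl", -1, "2007-02-09", 4, 3.0),
)


def demo_config(seed: int = 0) -> SyntheticConfig:
    """The demo study conditions: 14-26N winter-deep-north basin, six
    winters of daily data, satellite-like missingness heavier in the
    cloudy southern summer."""
    from mldchl.synthetic import MissingnessRule
    return SyntheticConfig(
        lat_min=14.0, lat_max=26.0, lon_min=34.0, lon_max=42.0,
        cell_deg=0.5, start="2002-10-01", end="2008-03-31",
        missing_base=0.25,
        missing_rules=(MissingnessRule(months=(6, 7, 8), lat_min=14.0,
                                       lat_max=19.0, p=0.55),),
        injections=DEMO_INJECTIONS, seed=seed,
    )


def load_demo():
    """Load the generated daily fields, bathymetry and region masks."""
    mld = read_grid(DATA / "mld_daily.nc", "mld")
    chl = read_grid(DATA / "chl_daily.nc", "chl")
    kd490 = read_grid(DATA / "kd490_daily.nc", "kd_490")
    bathy = read_bathymetry(DATA / "bathymetry.nc")
    regions = default_regions(14.0, 26.0)
    masks = {r.name: make_region_mask(bathy, r) for r in regions}
    return mld, chl, kd490, bathy, masks
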