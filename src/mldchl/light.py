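"""Euphotic depth from the diffuse attenuation coefficient.

The euphotic depth Z_e is the depth where photosynthetically available
radiation (PAR) falls to 1% of its surface value; under exponential decay
Z_e = ln(100)/K_d(PAR) = 4.605/K_d(PAR).  K_d(PAR) is obtained from the
satellite K_d(490) product by the clear-water relation

    K_d(PAR) = 4.6051 * K_d(490) / (6.07 * K_d(490) + 3.2),  K_d(490) <= 0.115 m^-1.

For turbid water, K_d(490) > 0.115 m^-1, no built-in conversion is applied:
those pixels are masked unless the caller supplies coefficients (a, b, c)
for K_d(PAR) = a * K_d(490) / (b * K_d(490) + c) from a source of their
choosing.  Comparing Z_e with the mixed layer depth (Z_e - MLD, positive
when the lit layer is deeper than the mixed layer) indicates where deep
mixing can dilute phytoplankton below the lit zone.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

__all__ = [
    "LN100",
    "KD490_BRANCH",
    "kd_par_from_kd490",
    "euphotic_depth",
    "ze_mld_difference",
]

LN100 = 4.605          # ln(100), 1% light level
KD490_BRANCH = 0.115   # m^-1, clear/turbid branch point


def kd_par_from_kd490(kd490: xr.DataArray,
                      high_branch_coeffs: tuple[float, float, float] | None = None
                      ) -> xr.DataArray:
    """K_d(PAR) from K_d(490); the turbid branch is masked unless supplied."""
    vals = kd490.values
    with np.errstate(invalid="ignore"):
        if np.any(vals <= 0):
            raise ValueError(
                f"kd_490 must be > 0 ({int(np.sum(vals <= 0))} offenders)"
            )
    low = vals <= KD490_BRANCH
    out = np.full_like(vals, np.nan, dtype=float)
    out[low] = 4.6051 * vals[low] / (6.07 * vals[low] + 3.2)
    if high_branch_coeffs is not None:
        a, b, c = high_branch_coeffs
        hi = ~low & np.isfinite(vals)
        out[hi] = a * vals[hi] / (b * vals[hi] + c)
    da = kd490.copy(data=out)
    da.name = "kd_par"
    da.attrs = {"units": "m-1",
                "high_branch": "masked" if high_branch_coeffs is None else "user"}
    return da


def euphotic_depth(kd_par: xr.DataArray) -> xr.DataArray:
    """Z_e = ln(100) / K_d(PAR), metres."""
    vals = kd_par.values
    with np.errstate(invalid="ignore"):
        if np.any(vals <= 0):
            raise ValueError("kd_par must be > 0 where defined")
    da = kd_par.copy(data=LN100 / vals)
    da.name = "z_eu"
    da.attrs = {"units": "m"}
    return da


def ze_mld_difference(ze_clim: xr.DataArray, mld_clim: xr.DataArray) -> xr.DataArray:
    """Per-pixel Z_e - MLD (m); positive = euphotic layer deeper than mixed."""
    if ze_clim.shape != mld_clim.shape:
        raise ValueError(
            f"misaligned climatologies: {ze_clim.shape} vs {mld_clim.shape}"
        )
    diff = ze_clim - mld_clim
    diff.name = "ze_minus_mld"
    diff.attrs = {"units": "m",
                  "sign": "positive = euphotic deeper than mixed layer"}
    return diff
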