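"""Generate the demo dataset: six winters of daily MLD, CHL and Kd490.

Writes gap-free model-like MLD, cloud-masked satellite-like CHL and Kd490
plus a shelf/basin bathymetry to scratch/demo, and the injected-extreme
ground-truth ledger to results/demo_injections.csv.
"""

import numpy as np

from _common import DATA, RESULTS, demo_config
from mldchl.grids import write_bathymetry, write_grid
from mldchl.synthetic import generate_fields


def main() -> None:
    cfg = demo_config(seed=0)
    mld, chl, kd490, bathy, ledger = generate_fields(cfg)

    DATA.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    write_grid(mld, DATA / "mld_daily.nc")
    write_grid(chl, DATA / "chl_daily.nc")
    write_grid(kd490, DATA / "kd490_daily.nc")
    write_bathymetry(bathy, DATA / "bathymetry.nc")
    ledger.to_csv(RESULTS / "demo_injections.csv", index=False)

    gap = float(np.isnan(chl.values).mean())
    print(f"{len(mld.time)} days on a {len(mld.lat)}x{len(mld.lon)} grid")
    print(f"MLD range {np.nanmin(mld.values):.1f}-{np.nanmax(mld.values):.1f} m; "
          f"CHL gaps {100 * gap:.1f}% of pixel-days")
    print(f"{len(ledger)} ground-truth extremes -> results/demo_injections.csv")


if __name__ == "__main__":
    main()
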