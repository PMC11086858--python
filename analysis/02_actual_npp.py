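#!/usr/bin/env python
"""Estimate actual NPP with the light-use-efficiency model.

Monthly NPP = APAR x (T_xi1 T_xi2 W_xi xi_max); the water scalar comes
from the annual humidity index K and accumulated temperature.  Writes the
monthly and annual NPP stacks plus the water-stress field to results/data/.
"""

from pathlib import Path

import numpy as np

from grassnpp import casa
from grassnpp.io_config import (
    RunConfig,
    load_monthly_cube,
    save_monthly_cube,
    write_raster_stack,
)

DATA = Path("results/data")


def main() -> None:
    cfg = RunConfig.from_file(DATA / "config.txt")
    n_years = len(cfg.years)
    temp, spec = load_monthly_cube(DATA / "temperature.tif", n_years=n_years)
    prec, _ = load_monthly_cube(DATA / "precip.tif", spec, n_years=n_years)
    sol, _ = load_monthly_cube(DATA / "solar.tif", spec, n_years=n_years)
    ndvi, _ = load_monthly_cube(DATA / "ndvi.tif", spec, n_years=n_years)

    act = casa.run_casa(temp, prec, sol, ndvi, cfg)
    save_monthly_cube(DATA / "na_monthly.tif", act.monthly, spec)
    write_raster_stack(DATA / "na_annual.tif", act.annual, spec)
    write_raster_stack(DATA / "w_xi.tif", act.w_xi, spec)

    mean_px = act.annual.mean(axis=0)
    print(f"actual NPP regional mean {np.nanmean(act.annual):.1f} g C m-2 a-1 "
          f"(pixel range {np.nanmin(mean_px):.0f}-{np.nanmax(mean_px):.0f})")
    print(f"water stress W_xi range {np.nanmin(act.w_xi):.3f}-{np.nanmax(act.w_xi):.3f}")


if __name__ == "__main__":
    main()
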