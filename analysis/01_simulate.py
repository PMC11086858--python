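#!/usr/bin/env python
"""Generate the synthetic study area: 50x50 km grid, 16 years of monthly
climate (NW->SE dry-cold to wet-warm gradient, +1.3 mm/a precipitation and
+0.01 degC/a temperature trends), NDVI responding to same-year climate,
and 102 survey points with observation error.

Writes raster stacks, the survey table and the run config to results/data/.
"""

from pathlib import Path

import numpy as np

from grassnpp import casa, synthetic
from grassnpp.io_config import RunConfig, save_monthly_cube, write_survey_csv

DATA = Path("results/data")


def main(seed: int = 1) -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    params = synthetic.SimParams(seed=seed)
    climate, ndvi = synthetic.simulate_inputs(params)
    spec = params.grid
    save_monthly_cube(DATA / "temperature.tif", climate.temperature, spec)
    save_monthly_cube(DATA / "precip.tif", climate.precip, spec)
    save_monthly_cube(DATA / "solar.tif", climate.solar, spec)
    save_monthly_cube(DATA / "ndvi.tif", ndvi, spec)
    cfg = RunConfig(years=params.years, seed=seed)
    cfg.to_file(DATA / "config.txt")

    truth = casa.run_casa(climate.temperature, climate.precip, climate.solar, ndvi, cfg)
    points = synthetic.generate_survey_points(
        truth.annual.mean(axis=0), 102, params.survey_noise_sd, seed, spec
    )
    write_survey_csv(DATA / "survey.csv", points.drop(columns=["row", "col"]))

    p_ann = climate.precip.sum(axis=1)
    print(f"grid {spec.n_rows}x{spec.n_cols}, years {params.years[0]}-{params.years[-1]}")
    print(f"regional annual precipitation: mean {p_ann.mean():.1f} mm, "
          f"pixel range {p_ann.mean(axis=0).min():.0f}-{p_ann.mean(axis=0).max():.0f} mm")
    print(f"regional mean annual temperature: {climate.temperature.mean():.2f} degC")
    print(f"wrote inputs and {len(points)} survey points to {DATA}/")


if __name__ == "__main__":
    main()
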