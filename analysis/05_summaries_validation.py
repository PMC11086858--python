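#!/usr/bin/env python
"""Descriptive summaries and validation.

Monthly/seasonal NPP accumulation profile, regional annual series with
trends for NPP/precipitation/temperature, and the regression of measured
survey NPP on modelled NPP.  Writes CSV tables to results/.
"""

from pathlib import Path

import pandas as pd

from grassnpp import summaries
from grassnpp.io_config import (
    RunConfig,
    load_monthly_cube,
    read_raster_stack,
    read_survey_csv,
)

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    cfg = RunConfig.from_file(DATA / "config.txt")
    n_years = len(cfg.years)
    na_monthly, spec = load_monthly_cube(DATA / "na_monthly.tif", n_years=n_years)
    na_annual, _ = read_raster_stack(DATA / "na_annual.tif", spec)
    prec, _ = load_monthly_cube(DATA / "precip.tif", spec, n_years=n_years)
    temp, _ = load_monthly_cube(DATA / "temperature.tif", spec, n_years=n_years)

    prof = summaries.seasonal_profile(na_monthly, cfg.seasons)
    pd.DataFrame({
        "month": range(1, 13),
        "npp_g_m2": prof.monthly_npp,
        "pct_of_annual": prof.monthly_pct,
    }).to_csv(OUT / "monthly_profile.csv", index=False)

    rows = []
    for name, field in (
        ("actual_npp", na_annual),
        ("precip", prec.sum(axis=1)),
        ("temperature", temp.mean(axis=1)),
    ):
        tr = summaries.regional_trend(field)
        rows.append({"variable": name, "mean": tr.mean, "min": tr.min,
                     "max": tr.max, "slope_per_year": tr.slope,
                     "slope_per_decade": tr.per_decade})
    trends = pd.DataFrame(rows)
    trends.to_csv(OUT / "annual_trends.csv", index=False)

    points = read_survey_csv(DATA / "survey.csv", spec)
    val = summaries.validate(na_annual.mean(axis=0), points)
    pd.DataFrame([val.__dict__]).to_csv(OUT / "validation.csv", index=False)

    shares = ", ".join(f"{k} {v:.1f}%" for k, v in prof.seasonal_pct.items())
    print(f"seasonal NPP shares: {shares}")
    print(f"Apr-Oct share of annual NPP: {prof.window_pct((4, 5, 6, 7, 8, 9, 10)):.1f}%")
    print(trends.to_string(index=False))
    print(f"validation: n={val.n} R2={val.r2:.3f} gain={val.gain:.2f} "
          f"intercept={val.intercept:.1f}")


if __name__ == "__main__":
    main()
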