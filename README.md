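# grassnpp

Quantifying how much of a grassland's productivity change is driven by
climate variability and how much by human activity, on gridded raster
time series.  The package implements the full chain used in regional
grassland assessments of the Qinghai-Tibet plateau margin:

1. **Actual NPP** (`Na`) from a light-use-efficiency (CASA-type) model
   driven by monthly NDVI and climate:
   `NPP(x,t) = APAR(x,t) · ξ(x,t)` with
   `ξ = T_ξ1 · T_ξ2 · W_ξ · ξ_max`, where the water scalar `W_ξ` comes
   from the grassland-classification humidity index `K = P / (0.1·Σθ)`
   (annual precipitation `P`, accumulated temperature `Σθ` over periods
   with mean temperature > 0 °C).
2. **Potential NPP** (`Np`) — the climate-determined productivity of the
   undisturbed climax vegetation — from a closed-form model in `P` and
   `Σθ` via `K` and the cubic `L(k)`.
3. **Human-induced NPP** by residual: `Nh = Np − Na`.
4. **Driver attribution**: per-pixel least-squares trend slopes
   `S_a, S_p, S_h` of the three annual series, classified into six
   restoration/degradation driver classes, with per-class area shares and
   NPP totals (Gg C a⁻¹).

A synthetic-data module generates gridded climate/NDVI/survey inputs with
the statistical structure the analysis assumes (NW→SE dry-cold to
wet-warm gradient, prescribed trends, injectable human pressure), so every
stage is testable without external downloads.  See `docs/methods.md` for
the model details, parameter defaults and design choices.

## Worked example

The analysis scripts run the whole study on the default synthetic area
(50×50 km grid, 2000–2015):

```sh
python analysis/01_simulate.py
python analysis/02_actual_npp.py
python analysis/03_potential_npp.py
python analysis/04_attribution.py
python analysis/05_summaries_validation.py
python analysis/06_driver_recovery.py
```

which prints, among other things:

```
regional annual precipitation: mean 309.8 mm, pixel range 111-510 mm
actual NPP regional mean 232.9 g C m-2 a-1 (pixel range 72-396)
water stress W_xi range 0.743-0.903
frozen variant: mixed_poly (689.7 g m-2 a-1 at the regional-mean climate)
restored pixels: 2252, degraded pixels: 248 (of 2500)
seasonal NPP shares: spring 12.4%, summer 70.7%, autumn 16.7%, winter 0.1%
validation: n=102 R2=0.797 gain=0.92 intercept=25.5
climate-only degradation: 99.9% of classified pixels in climate classes 5/6
human-only degradation:  95.4% of classified affected pixels in human class 4
```

Reading: under the default (mildly wetting) climate most pixels classify
as restoration; the validation regression of 102 noisy survey points on
modelled NPP recovers the tuned R² ≈ 0.8; and the injected drought /
grazing scenarios are attributed to the correct driver classes.  Tables
land in `results/` (`attribution_summary.csv`, `annual_trends.csv`,
`monthly_profile.csv`, `validation.csv`, `driver_recovery.csv`).

The same stages are available as a CLI over a data directory:

```sh
grassnpp simulate --seed 42 --out data/
grassnpp actual-npp --data data/
grassnpp potential-npp --data data/
grassnpp attribute --data data/
grassnpp summarize --data data/
grassnpp validate --data data/
```

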