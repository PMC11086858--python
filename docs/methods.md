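# Methods

## Models

### Actual NPP (light-use efficiency)

Monthly actual NPP is the product of absorbed photosynthetically active
radiation and a realised light-use efficiency,

    Na(x, m) = APAR(x, m) · ξ(x, m),      ξ = T_ξ1 · T_ξ2 · W_ξ · ξ_max.

APAR is `SOL · FPAR · 0.5`: half of incident solar radiation is
photosynthetically active, and the absorbed fraction is a linear rescale
of NDVI, `FPAR = clip((NDVI − ndvi_min)/(ndvi_max − ndvi_min), fpar_min,
fpar_max)` with defaults `ndvi_min = 0.05`, `ndvi_max = 0.95`,
`fpar_max = 0.95`.  The temperature stresses are the standard CASA forms

    T_ξ1 = 0.8 + 0.02·T_opt − 0.0005·T_opt²
    T_ξ2 = 1.1814 / [(1 + e^{0.2(T_opt−10−T)}) (1 + e^{0.3(−T_opt−10+T)})]

with `T_opt` the mean temperature of the month with the year's peak NDVI
at that pixel.  The water scalar replaces CASA's soil-moisture sub-model
with a closed form in the annual humidity index `K = P/(0.1·Σθ)` and
accumulated temperature `Σθ`:

    W_ξ = 0.5 + 0.5 · [(0.29√K + 0.6)(K·L(K) + 0.469·K^{3/2} + 9.33/Σθ)]
                    / [(K + 0.469√K + 0.966)(L(K) + 0.933/K)]
    L(K) = K + 0.906·K^{−1/2} + 0.22

computed once per pixel-year (it depends only on annual quantities) and
applied to all 12 months.  The printed source of this equation is
typographically ambiguous in its grouping; the grouping above is the one
that gives the physically sensible limits — the ratio vanishes as K → 0⁺
(the 0.933/K term dominates the denominator), so W_ξ → 0.5 at extreme
aridity — and the function is isolated so alternative parses can be
swapped.  Because the ratio grows without bound in K, W_ξ is clipped to
`[0.5, 1.0]` (configurable).  `ξ_max` defaults to 0.542 g C MJ⁻¹, a
single-class grassland maximum; per-class maxima can be supplied by
running the model per class mask.

`Σθ` is accumulated from monthly means as `Σ max(T_m, 0) · days-in-month`
(365-day calendar); a daily basis is supported where daily data exist.
Monthly compositing of half-month NDVI uses the maximum-value composite,
the standard choice for NDVI synthesis.

### Potential NPP (climate-only closed form)

Potential NPP uses the synthetic-vegetation model

    Np = RDI² · P · (1 + RDI + RDI²) / [(1 + RDI)(1 + RDI²)] · e^{E} · 100

with the radiative dryness index expressed through the classification
humidity index, `RDI = L(k)/k³`,
`L(k) = 0.58802k³ + 0.50698k² − 0.0257081k + 0.0005163874`, and
`k = P/(0.1·Σθ)`.  Multiplying through by k⁶ gives the equivalent bracket
form `L²·0.1Σθ·[k⁶+Lk³+L²] / ([k⁶+L²][k⁵+Lk²])·e^E·100`; the factor 100
converts the lineage's t DM hm⁻² a⁻¹ to g m⁻² a⁻¹.  RDI decreases from
large values at k → 0 (arid) to 0.588 as k → ∞ (humid), so the model is a
moisture-limited production curve scaled by precipitation.

The exponent E survives in print only in a degraded form that admits
several readings.  Rather than guessing silently, the package keeps a
registry of five named variants — polynomial readings in k and k⁻¹, the
literal transcription, and the lineage's original `−√(9.87 + 6.25·RDI)` —
and freezes one by two gates evaluated at run time:

* **monotonicity**: Np must be non-decreasing in P at fixed Σθ over the
  study envelope P ∈ [100, 500] mm, Σθ ∈ [800, 2000] °C·d;
* **magnitude**: at the reported regional-mean climate (P = 448.2 mm and
  Σθ = 1107.775 °C·d, the accumulation implied by the reported mean annual
  temperature −2.1 °C with a 12.5 °C seasonal half-amplitude), Np must lie
  inside the reported regional annual range [536.1, 812.1] g m⁻² a⁻¹.

Two variants fail monotonicity, two fail magnitude; `mixed_poly`
(E = −13.55 + 3.17k − 0.16k² + 0.0032k⁻³) passes both uniquely, landing
at 689.7 g m⁻² a⁻¹.  Rejections are logged with reasons; the frozen name
is written next to every potential-NPP output.  Negative or non-finite
evaluations are clipped to 0 and logged (Np is a production quantity);
P = 0 returns 0 by contract, Σθ ≤ 0 is masked.

The frozen form is steep in k.  On the synthetic grid the joint
precipitation/temperature gradient yields per-pixel k ≈ 2.0–2.8, below
the effective regional k ≈ 4.0 of the calibration point, so synthetic
per-pixel Np is numerically small (tens of g m⁻²).  Nothing downstream
depends on that magnitude — attribution uses only the slopes' signs — but
absolute synthetic Np values should not be read as regional estimates.

### Residual attribution

`Nh = Np − Na` per pixel-year.  Trend slopes use the closed-form
least-squares estimator against the year index i = 1..n,

    S = [n·Σ(i·NPP_i) − Σi·ΣNPP_i] / [n·Σi² − (Σi)²],

identical (to ≤1e-10 relative) to a polynomial least-squares fit.  Since
the slope operator is linear, `S_h = S_p − S_a` identically.

The published six-class sign table is stated in terms of S_h, but its
triples (e.g. class 1: S_a>0, S_p<0, S_h>0) are algebraically unreachable
under S_h = S_p − S_a, while the accompanying text reads S_h > 0 as
"human activities improved restoration".  The default
`residual_consistent` mode therefore classifies on the human-effect sign
H = S_a − S_p (= −S_h), which makes all six classes reachable and
exhaustive:

| class | meaning | rule (ε = slope zero-tolerance) |
|---|---|---|
| 1 | restoration, human-driven   | S_a > ε, S_p < −ε |
| 2 | restoration, climate-driven | S_a > ε, S_p > ε, H < −ε |
| 3 | restoration, climate+human  | S_a > ε, S_p > ε, H > ε |
| 4 | degradation, human-driven   | S_a < −ε, S_p > ε |
| 5 | degradation, climate-driven | S_a < −ε, S_p < −ε, H > ε |
| 6 | degradation, climate+human  | S_a < −ε, S_p < −ε, H < −ε |

Any deciding slope within ε of zero → unclassified (code 0).  ε defaults
to 0 (strict inequalities, as published); raise it for noisy data.  The
literal table remains available as `classification_mode=table_literal`.

Per-class aggregates report area as a percentage of the class's group
(restored 1–3 or degraded 4–6) and NPP totals as `Σ Na·pixel_area` in
Gg C a⁻¹ using the multi-year mean annual Na per pixel (the source study
does not state which year its totals use).

### Summaries and validation

Seasonal profiles use a configurable season→month mapping (default
meteorological MAM/JJA/SON/DJF).  The source study's own mapping is
internally inconsistent (it labels June–August "autumn"), so seasonal
shares are descriptive, not calibration targets.  Regional trends are
plain means over equal-area pixels, with per-decade values as slope×10.
Validation regresses measured survey NPP on modelled NPP at the sampled
pixels (ordinary least squares, R² reported); zero variance in either
variable is signalled rather than silently returning 0 or 1.

## Synthetic study area

The generator emulates the structure of station-interpolated climate
grids and composited satellite NDVI for a semi-arid alpine region:

* **Grid**: 50×50 pixels of 1 km², 16 years × 12 months.
* **Precipitation**: base gradient 100→500 mm a⁻¹ from NW to SE along
  the diagonal, trend +1.3 mm a⁻¹, i.i.d. pixel-year noise sd 10 mm,
  disaggregated by fixed monthly weights putting 70 % in June–September.
* **Temperature**: annual-mean gradient −6.0→+1.8 °C (regional mean
  −2.1 °C), trend +0.01 °C a⁻¹, sinusoidal seasonal cycle of half-
  amplitude 12.5 °C peaking in July (giving January ≈ −14.6 °C and July
  ≈ +10.4 °C at the regional mean, consistent with high-altitude
  climatology), i.i.d. monthly noise sd 0.2 °C.
* **Radiation**: spatially uniform seasonal cycle 300–700 MJ m⁻² month⁻¹.
* **NDVI**: annual greenness G = 0.05 + 0.50·(P/500) + 0.05·(T_JJA/10)
  + h + noise (sd 0.02), spread over months by a fixed seasonal shape
  peaking in July and clipped to [−1, 1].  The response coefficients are
  free simulation parameters — the source material quantifies no
  NDVI–climate coupling — chosen to give peak NDVI ≈ 0.18 (arid NW) to
  ≈ 0.6 (humid SE) and actual NPP of the right order (~10²  g C m⁻² a⁻¹).
* **Human pressure** h(x, year) is added to NDVI only, so it propagates
  to actual NPP but never to the climate-only potential NPP.  Default
  zero; scenarios inject an offset/trend inside a block (default the NW
  quadrant).
* **Surveys**: n points sampled uniformly without replacement from valid
  pixels; measured = true NPP + N(0, σ).  `noise_sd_for_r2` returns the σ
  giving an expected validation R² via var(signal)/(var(signal)+σ²).

The noise sds are deliberately small: interpolated climate surfaces are
smooth, and pixel-level interannual residuals in such products are far
below raw station variability.  The generator omits several features of
real data — spatially correlated weather anomalies shared across the
region, topographic covariates, NDVI saturation and snow contamination,
grassland-class heterogeneity in ξ_max — so passing tests demonstrate the
pipeline's correctness and the attribution logic's identifiability under
its own assumptions, not performance on real imagery.

Determinism: all randomness flows through seeded generators; climate,
NDVI and survey noise use independent child streams of the same seed, so
identical parameters give identical outputs byte-for-byte.

### Scenario presets

* `scenario_climate_degradation`: precipitation trend −3 mm a⁻¹
  grid-wide (a sustained drought), no human term.  Expectation: affected
  pixels classify into the climate classes 5/6.
* `scenario_human_degradation`: NDVI suppressed by 0.006 a⁻¹ in the NW
  block while climate keeps its default trends.  The mild default wetting
  keeps S_p > 0, which is what makes the human class 4 (S_a < 0, S_p > 0)
  reachable: under a perfectly trendless climate S_p ≈ 0 and the strict
  sign rules would leave degraded pixels unclassified rather than
  attribute them.

Observed recovery (100 replicates, 20×20 grid): 99.9 % of classified
pixels in classes 5/6 under drought; 95.4 % of classified affected pixels
in class 4 under grazing pressure.

## Numerical choices

* Missing data are NaN in memory; the nodata sentinel (−9999) exists only
  on disk.  NaN propagates through all arithmetic; any masked month masks
  the annual pixel.
* W_ξ clip [0.5, 1.0]; FPAR clip [0, 0.95]; NDVI clip [−1, 1]; negative
  potential NPP clipped to 0 with a logged count.
* All-NaN NDVI years fall back to month 1 for T_opt; the pixel's NPP is
  NaN regardless, so the choice is inert.
* Slope requires n ≥ 2; classification treats NaN slopes as unclassified.
* Rasters are stored float32; round-trips are bit-exact at that width.

## Problem sizes

The analysis scripts use the full 50×50 grid; the test suite and the
acceptance script run Monte-Carlo loops (100 replicates) on 10×10–20×20
grids, sizes at which every statistical check is already stable (the
3-standard-error recovery bands are met with wide margins) while the
whole suite completes in seconds.

## Known limitations

* The exponent of the potential-NPP closed form is reconstructed by a
  gated selection, not recovered from a clean source; the frozen variant
  is steep in k, and per-pixel potential NPP on climates far from the
  calibration point should be treated as ordinal rather than absolute.
* No significance testing on slopes (none is attached in the source
  methodology); a robust Theil–Sen alternative would be a natural
  extension.
* Survey NPP is taken directly in NPP units; biomass-to-carbon conversion
  is out of scope.
* One projected grid; no reprojection or polygon boundary handling.
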