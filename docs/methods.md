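# Methods

## Model

`sandfix` maps soil loss by wind with the revised wind erosion equation
(RWEQ), an empirical transport-capacity model. Five factor layers multiply
into a capacity term `P = WF · EF · SCF · K' · C`:

- **WF** (kg/m) — the climate factor. Per calendar month,
  `Wf = u2 (u2 − u1)² Nd` (m³/s³) from the monthly mean 2-m wind `u2`, the
  erosive threshold `u1 = 5 m/s` and the count `Nd` of days whose 2-m wind
  exceeds the threshold; the monthly contribution is
  `Wf · (ρ/g) · SW · SD`, with air density
  `ρ = 348 (1.013 − 0.1183 EL + 0.0048 EL²)/T`, soil wetness
  `SW = (ETp − (R+I) Rd/Nd_days)/ETp` clamped to [0, 1], and snow factor
  `SD = 1 − P(snow depth > 25.4 mm)`. WF is the sum over the months of the
  period. Station wind measured at 10 m is converted to 2 m with the FAO
  logarithmic-profile factor `4.87 / ln(67.8 z − 5.42)`.
- **EF** — soil erodible fraction,
  `(29.9 + 0.31 Sa + 0.17 Si + 0.33 Sa/Cl − 2.59 OM − 0.95 CaCO3)/100`.
- **SCF** — soil crust factor, `1/(1 + 0.0066 Cl² + 0.021 OM²)`.
- **K'** — surface roughness, `exp(1.86 Kr − 2.41 Kr^0.94 − 0.127 Crr)` with
  the Smith–Carson ridge roughness `Kr = 0.2 ΔH²/L` (ΔH the focal elevation
  range within L = 1 km), expressed in cm.
- **C** — vegetation factor `exp(ai · SC · 100)` with `ai = −0.0438` per
  percent cover; fractional cover SC comes from NDVI pixel dichotomy,
  `(NDVI − NDVI_soil)/(NDVI_veg − NDVI_soil)` with the 5th/95th percentile
  endpoints when not supplied.

Transport capacity and field-length scale:
`Qmax = 109.8 P` (kg/m), `s = 150.71 P^−0.3711` (m), and the soil loss at
downwind distance `z` is `SL = (2z/s²) Qmax exp(−(z/s)²)` (kg/m²).
Potential erosion **SLR** runs the same chain with `C = 1` (bare surface);
the wind-erosion prevention service is **WEPS = SLR − SL** and the retention
rate **F = WEPS/SLR × 100** (%, undefined where SLR = 0).

Driver attribution uses the geographical-detector family on the SL field:
the q statistic `q = 1 − ΣNh σh²/(N σ²)` with population variances (so the
decomposition telescopes and q ∈ [0, 1] exactly), the interaction detector
(q of the cross-classification, labelled enhance/independent/weaken against
q1 + q2), Welch t tests on stratum means (risk detector), and an F-ratio
test on two factors' within-strata variance sums (ecological detector).

Field validation classifies measured/predicted soil-loss pairs with a ±50%
relative criterion (closed interval: a prediction exactly at the bound
counts as accurate) and fits per-site-type OLS calibration lines of
predicted on measured, reporting R² (squared Pearson correlation) and RMSE.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `u1_threshold` | 5 m/s | erosive 2-m wind threshold |
| `ai` | −0.0438 /% | vegetation suppression coefficient |
| `ef_constant` | 29.9 | EF equation constant (29.09 = canonical RWEQ) |
| `kprime_exponent` | 0.94 | K' exponent (0.934 = canonical RWEQ) |
| `cover_scale` | percent | scale of cover in `C = exp(ai·cover)` |
| `z_m` | 50 m | downwind distance of maximum erosion |
| `roughness_length_m` | 1000 m | focal window radius for ΔH |
| `idw_power`, `idw_k` | 2, all | IDW weighting and neighbour count |
| `alpha` | 0.05 | significance level of risk/ecological tests |
| driver classes | 10 (5 for population/GDP) | discretisation class counts; soil type passes through |

Notes on genuinely open choices, resolved as follows:

- **Wf below threshold** is defined as 0 (the squared term alone would make
  sub-threshold wind erosive).
- **WF aggregation** is monthly summaries summed to an annual value.
- **SW clamping** to [0, 1]: moisture suppression cannot exceed total
  suppression in wet months.
- **ETp** is accepted as a direct monthly input or computed as
  `0.0162 (SR/58.5)(DT + 17.8)` from monthly solar radiation (cal/cm²) and
  mean temperature (°C) — the standard RWEQ form.
- **Cover scale.** With `ai` applied to fraction-scale cover, C would span
  only [0.957, 1] and vegetation could never produce the strong east–west
  service contrast the model is meant to express; cover is therefore taken
  in percent. The literal fraction reading remains available via
  `cover_scale="fraction"`.
- **Exponent grouping** in the field-length equation: the −0.3711 exponent
  applies to the full factor product, not to K' alone — otherwise `s` would
  be insensitive to climate and soil, contradicting the flux equation's
  structure.
- **Kr units**: ΔH and L enter in meters and Kr is converted to cm, the unit
  the K' coefficients expect.
- **Wet days** are days with ≥ 0.1 mm precipitation; irrigation is 0 where
  unrecorded.
- **Ecological detector decision rule**: two-sided F test at level α with
  (N₁−1, N₂−1) degrees of freedom, which makes the Y/N table symmetric under
  factor exchange.
- **Interaction "independent" tolerance**: |q12 − (q1+q2)| < 1e-9.
- **Rank ties** share a dense rank rather than being broken arbitrarily.
- **Pipeline interpolation**: the annual climate factor is computed per
  station from its own monthly summaries and then IDW-interpolated, rather
  than interpolating each daily variable first. The factor chain up to WF is
  per-station scalar algebra, so the two orders differ only through IDW's
  weighted averaging; interpolating the finished WF keeps every station's
  wind–wetness–snow coupling intact.

## Synthetic scenes

`generate_scene` produces the study conditions for all tests: a 1-km grid
with (i) a west→east NDVI gradient (bare dunes to vegetated margin) with a
summer-peaking seasonal cycle, (ii) spatially smooth sandy texture closing
to 100% with organic matter rising eastward, a 5-class soil-type map
thresholded from texture, (iii) a gentle DEM (local relief well under the
~60 m/km beyond which the exponential K' form diverges — the model's known
pathology, not the generator's), (iv) two land-cover epochs classified from
NDVI with perturbed boundaries so the transition matrix is non-trivial, and
(v) stations with Weibull daily wind whose March–May scale puts the monthly
mean 2-m wind moderately above the 5 m/s threshold (erosive days present
but far from saturated), sinusoidal temperature, sparse summer rain and
occasional winter snowpack. All randomness derives from one
`numpy.random.Generator`; equal seeds give bit-identical scenes.

What the scenes do **not** emulate: real climatology or its interannual
structure, spatially correlated measurement error, NDVI phenology beyond a
single harmonic, real soil taxonomy, or any administrative geography.
Passing tests therefore demonstrate correctness of the computational chain
and recoverability of planted signals, not predictive skill on real
landscapes — that is what the field-validation table is for.

`plant_driver_response` plants a response on a stratification with an exact
between-class variance: class means are drawn normally and rescaled so
their variance equals `between_var` before iid cell noise of variance
`noise_var` is added. The rescaling keeps the expected q at
`between/(between + within)` even for modest class counts, where a raw draw
would bias q low (Jensen's inequality on the ratio).

## Numerical choices

- Rasters are float64 in memory; nodata is −9999 on disk (ESRI ASCII grid,
  `%.17g` so round trips are bit-identical), NaN in computation.
- Cells with a non-positive factor product have no defined field length and
  propagate as nodata through SLR/SL/WEPS/F; F is nodata where SLR = 0.
- IDW returns the station value exactly when a cell center lies within
  1e-9 m of a station.
- Discretisation reduces k with a warning when a layer has fewer distinct
  values; a constant layer raises a degenerate-strata error.
- Strata with fewer than 2 samples are excluded from the risk detector with
  a warning; q simply sums over whatever strata are present.
- Natural-breaks discretisation is a deterministic 1-D k-means (quantile
  initialisation), a Fisher–Jenks analogue.

## Problem sizes

The shipped test-suite and acceptance runs use 16–40 cell grids for
chain-level checks, 100×100 grids (10⁴ cells, 20 seeds) for planted-driver
recovery, and the 60×60 default grid for the end-to-end determinism run —
sizes at which every Monte-Carlo tolerance in the tests is comfortably
resolved.

## Known limitations

- The exponential K' form grows without bound for ridge roughness above
  ~75 cm; the package computes it as specified and leaves terrain
  plausibility to the caller.
- The flux curve is non-monotone in the factor product once `s < z/1.53`;
  with C ≤ 1 this could in principle invert the potential/actual ordering at
  extreme products (far beyond the calibrated range of the coefficients).
- The mobile-dune calibration line of the packaged observation table is not
  asserted anywhere: the four dune pairs alone do not reproduce a
  published fit under either regression orientation, so only the farmland
  line is treated as a check.
- No reprojection beyond affine grid alignment; all layers must share a
  projected CRS.
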