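# Methods

## The separation model

Total PM2.5 at location `s` on day `t` is treated as the sum of a fire
component `PM_F` and a background `PM_B`. Neither is directly observable:
monitors measure only the total. The identifying assumptions are

1. cell-days can be labeled *smoke-impacted* or *no-smoke* from information
   independent of the ground monitors — a satellite plume polygon overhead,
   or a with-fire/no-fire CTM pair whose simulated smoke share exceeds 0.03
   (strict inequality; the union of the two rules, so either alone
   suffices);
2. on no-smoke cell-days the fire component is negligible, so a regressor
   `f` trained there on observed PM2.5 learns the background process;
3. `f` extrapolates into the smoke region, because its predictors (no-fire
   CTM run, AOD, meteorology, land use) are available and meaningful there
   too.

A second regressor `f'`, trained only on smoke-impacted cell-days with the
with-fire CTM run and plume features added, estimates the total; smoke is
the difference `max(f' − f, 0)`. Negative raw differences are a model-error
diagnostic, not a physical signal — they are floored at zero and counted
(the count is logged, stored on the model, and echoed in the run manifest).

Both regressors are random forests (scikit-learn
`RandomForestRegressor`). Defaults: 300 trees, `ceil(p/3)` candidate
features per split, minimum leaf size 3, all exposed in `PipelineConfig`.
300 trees is the point where out-of-fold R² plateaus on the default
synthetic study while keeping a 20-fold × 2-model cross-validation
tractable on a single core; forests are insensitive to the exact count well
before that.

## Oversampling rare high concentrations

Monitor archives contain very few high-concentration days, so the forests
would underfit peaks. Training rows are augmented with a regression
extension of SMOTE: a row with target strictly between 35 and 100 µg/m³
receives one synthetic copy, a row strictly above 100 receives two. A
synthetic row is `parent + u·(neighbour − parent)`, `u ~ U(0,1)`, applied
jointly to features and target, with the neighbour drawn uniformly from the
parent's five nearest same-stratum rows in standardized feature space
(classical SMOTE interpolates class labels and cannot be used for a
continuous target, hence the joint interpolation). The output size is
exactly `n + n_(35,100) + 2·n_(>100)`. During cross-validation the
augmentation runs inside each training fold only, so no synthetic row ever
descends from a held-out parent. One-member strata are duplicated verbatim
with a warning. The oversampled fraction is reported; on the default
synthetic study it is below 1 %, consistent with high days being rare.

## Sensor calibration

Dual-channel low-cost optical sensors over-read PM2.5 with humidity- and
temperature-dependent bias. The pipeline:

- **Hourly QC / daily aggregation.** A sensor-day survives iff each channel
  has ≥ 16 of 24 hourly values, the symmetric relative difference of the
  channel daily means `|Ā−B̄| / ((Ā+B̄)/2)` is ≤ 0.30, the daily mean is
  ≤ 1000 µg/m³, and daily temperature/RH lie in [−20, 140] °F / [0, 100] %.
  The 30 % rule is applied to daily channel means, and the completeness
  rule per channel (both must qualify) — the stricter reading where the
  convention is ambiguous, both configurable. Reference monitors get only
  the completeness rule.
- **Pairing.** Each sensor is matched to the nearest reference monitor
  within 5 km (ties to the smaller station id); pairs form on days both
  report.
- **Regional GWR.** The domain is split into four rectangular regions; in
  each, `reference ~ 1 + raw + RH + T` is fitted by locally weighted least
  squares with Gaussian kernel weights `exp(−(d/bandwidth)²)`, pooled over
  days (a per-day refit is configurable but needs far more pairs per day
  than a desk-scale network provides). Bandwidth defaults to 15 km at the
  synthetic domain scale and is a config knob; the regression has no
  kernel-truncation cutoff.
- **Blending.** Within 20 km of a region boundary the calibrated value is
  the unweighted mean of all adjacent regions' predictions (two at an edge,
  up to four at the corner), making the correction continuous across
  boundaries when the regional models agree. Calibrated values are floored
  at 0, and only those strictly above 12 µg/m³ supplement the reference
  network in model training — low values add little information where the
  reference network already constrains the model, while high values are
  exactly what the archives lack.

## Data integration

All products meet on the common 1-km grid. Coarse fields are interpolated
by inverse-distance weighting over the k = 4 nearest nodes with power 2
(exact collocation returns the node value). Cloud-masked satellite AOD is
gap-filled in two steps: a pooled linear regression of observed AOD on the
regridded coarse AOD and meteorology fills gaps with fitted values, then a
3×3 spatial mean smooths the filled cells only; observed cells pass through
untouched. This gap-fill is a deliberately simple stand-in behind a single
interface — it assumes spatial continuity and a stable AOD–covariate
relationship, and a more elaborate scheme can be swapped in without
touching the callers. Plume polygons rasterise to per-cell duration (sum of
overpass windows across covering polygons, capped at 24 h) and
duration-weighted mean density class; a cell is "covered" when its center
lies inside the polygon, boundary inclusive — area-overlap weighting is not
attempted at 1-km resolution. Ground observations (reference plus selected
calibrated sensor-days) are averaged within each cell-day.

## The synthetic world

The generator emulates the statistical structure the analysis relies on,
not the physics:

- **Background:** positive baseline (8 µg/m³) + seasonal sinusoid
  (±3 µg/m³) + smooth spatial Gaussian random field (sd 2, 10-km
  correlation) + day-to-day term + small temperature/RH response, floored
  at 0.
- **Smoke:** discrete events (8 per 120-day year, 2–8-day lifetimes,
  lognormal peak strength with median ≈ 20 µg/m³) adding
  `strength · exp(−distance/decay)` around a drifting center, decay 3–10
  km. Smoke is exactly zero off event days, so truth recovery is
  well-posed.
- **Plume polygons** are drawn as the convex hull (buffered by 0.6 cell) of
  each event-day's cells above 2 µg/m³ of event smoke, with density class
  1/2/3 by terciles of event-day peak — guaranteeing label–truth
  consistency, which real satellite analysts approximate but a generator
  can enforce.
- **CTM pair:** truth fields times `exp(ε)` with spatially correlated
  zero-mean log errors (sd 0.25); the two runs share 90 % of their error
  variance (same meteorology and non-fire emissions), and the total run is
  floored at the background run. With independent errors the smoke-ratio
  label would fire on half of all truly smoke-free cell-days; at 0.9 the
  smoke region still covers roughly half of all cell-days, matching the
  prevalence the labeling rule produces on real archives.
- **Satellite AOD** is an affine function of total PM2.5 plus retrieval
  noise large enough that AOD is a *weaker* predictor than the CTM runs (a
  column quantity never tracks surface PM tightly); cloud fraction above
  0.6 masks it. A coarse reanalysis-style AOD (every 5th cell, 10 %
  multiplicative error) supports gap-filling.
- **Monitors:** reference sites sample cells with probability ∝ population
  (urban bias); low-cost sites with exponent 0.3 (more dispersed).
  Reference monitors report hourly truth + N(0, 1) µg/m³; low-cost channels
  report `truth·1.35 + 0.05·RH + 0.02·T + N(0, 2)` per channel. About 1 %
  of sensor-days are degraded (exactly 15 hours, divergent channels, or
  impossible values) to exercise QC.
- **Calendar:** three 120-day "years", so 3-year design values exist at
  desk scale; no formula depends on calendar realism. Coordinates are
  planar km; the 5- and 20-km radii are Euclidean, faithful at these
  scales.

What the generator does *not* emulate: atmospheric chemistry and transport,
emission inventories, geodesy, instrument drift, satellite orbit geometry,
or the spatial extent of a continent. Passing recovery tests therefore
demonstrate that the estimator is consistent when its structural
assumptions hold — that the labeling rule, the two-model difference, the
calibration and the metrics are implemented correctly — not that real-world
accuracy matches the synthetic numbers. In particular the synthetic CV R²
(≈ 0.93–0.96) exceeds what heterogeneous real archives allow.

## Evaluation

Overall CV partitions observed rows at random into 20 folds; spatial CV
partitions sites (grid cells here — the natural unit when observations are
cell-assigned), temporal CV partitions calendar dates. R² is
`1 − SS_res/SS_tot` on the pooled out-of-fold predictions, RMSE likewise
pooled. Monthly/annual aggregation averages obs and prediction per
site-period (30-day blocks / study years; ≥ 1 observed day per site-period,
configurable) before computing R² — with day-level errors roughly
independent, aggregation raises R², and the size of the rise indicates how
much of the daily error is random rather than systematic.

## Exposure and attainment metrics

- A **smoke-impact day** has smoke strictly above 25 % of estimated total
  PM2.5 (days with zero total never count). "Affected for more than a
  month" means ≥ 30 impact days in a year (configurable; in a 120-day
  synthetic year this is deliberately a much harsher bar than in a
  365-day year, and the default study reports a zero fraction while mean
  impact days stay informative).
- The **vicinity mask** marks cells within 5 km of any reference monitor;
  population-weighted impact days and concentration means are reported per
  stratum, per year. A person is *smoke-impacted* in a year if their cell
  has ≥ 1 impact day (threshold configurable; the source convention is
  unstated).
- The **multi-year summary** reports unweighted column means over years and
  the headline vicinity contrast as the **mean of yearly percent
  differences** — not the percent difference of the means. The two
  conventions differ measurably (a two-year fixture with days (10, 20) and
  (20, 20) gives 50 % vs 33 %), and only the mean-of-ratios convention
  reproduces the published 36.5 % average from the published yearly rows.
  On that table the yearly excess ranges from −8 % (2018) to 77 % (2010) as
  computed; the summary reports the computed extrema. Years with zero
  in-vicinity impact days are excluded from the excess with a warning.
- **Design values** are trailing 3-year means of annual means;
  **nonattainment** is design value ≥ threshold (inclusive), evaluated with
  smoke (total field) and without (total minus smoke), at 9 and 10 µg/m³.
  Dominance (with-smoke ⊇ without-smoke; counts nonincreasing in the
  threshold) holds by construction and is asserted in tests.

## Numerical and design notes

- All randomness flows from one global seed through
  `SeedSequence(seed, spawn_key=(stage_index,))`, so each stage is
  independently reproducible and every derived seed stays below 2³¹.
- IDW weights use `d⁻²` with an exact-collocation short-circuit at
  `d < 10⁻¹²` km.
- The channel-agreement ratio treats a 0/0 (both channels exactly zero) as
  perfect agreement.
- GWR solves the weighted least squares by `lstsq` on the
  `sqrt(w)`-scaled design; a rank-deficient design raises with the region
  id. Fit requires ≥ 5 pairs (p + 1).
- Labels, thresholds and strata use strict inequalities where the source
  wording is "over"/"greater than" (12, 0.03, 35, 100, 25 %) and an
  inclusive one for attainment ("equal to or above"); each is a config
  field, echoed into the run manifest.
- Day indices are 0-based; intervals are half-open, including plume hour
  windows `[start_hour, end_hour)`.
- Feature tables persist as parquet inside run directories for speed; the
  observation tables, plume GeoJSON, gridded NetCDF (day, y, x) and JSON
  summaries are the interchange formats, each with exact round-trip tests.

## Known limitations

- The background model extrapolates into the smoke region; if smoke-region
  background systematically differs from anything seen in training (e.g.
  fires correlated with stagnation), the difference estimator inherits that
  bias. The synthetic world draws fire events independently of the
  background process, so this failure mode is not exercised.
- The gap-fill stand-in is linear and local; real retrieval gaps are
  correlated with aerosol conditions (clouds near fronts), which a linear
  fill underestimates.
- Negative total-minus-background differences (typically ~20 % of
  smoke-region cell-days, mostly where true smoke is near zero) are floored
  rather than modeled; the count is the diagnostic.
- Monitor fractions and attainment populations at desk scale depend
  strongly on the handful of synthetic monitors; they are reported as
  computed, without any claim of correspondence to continental values.
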