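# Methods

This note records what `pbpah` computes, the parameter choices that are
package decisions rather than published facts, and the known limitations
of the synthetic-data generator.

## Problem and model

Particle-bound polycyclic aromatic hydrocarbon (PB-PAH) exposure varies
over minutes as people move between microenvironments: in-vehicle
concentrations are an order of magnitude above indoor ones. The package
reconstructs personal exposure determinants from three linked streams —
15-s GPS fixes, 1-min PB-PAH concentrations, and GIS traffic covariates —
and models the square root of period-mean concentration at three
aggregation levels:

1. **person-day** — OLS on covariates built per subject and calendar day,
   plus a linear mixed model with a subject random intercept and an
   independent random slope on the in-vehicle fraction (repeated days are
   clustered within subjects);
2. **subject** — OLS on minute-weighted subject averages;
3. **subject × time-activity category** — OLS on per-category averages
   (indoor / in-vehicle / other) with ≥ 60 min of data per cell.

The outcome is `sqrt(mean(concentration))` — the square root is applied
*after* averaging. All percent-time covariates are fractions in [0, 1].

## Pipeline stages

**Projection** (`pbpah.projection`). Geodetic ↔ projected coordinates use
a hand-written transverse Mercator (UTM zone 11N, GRS80/NAD83) via the
Krüger series in the third flattening (6th order, mm-level accuracy).
This replaces an external projection library; it is oracle-tested against
a closed-form meridional-arc distance and exact round-trips.

**Time-activity classification** (`pbpah.gps_processing`). Each 15-s fix
is labelled from the centred rolling-median speed v (window 5) and
proximity to dwell anchors (home/work, radius 50 m): `v > 8 km/h` →
in-vehicle; `v < 2 km/h` near an anchor → indoor; otherwise other. Fixes
are fused to calendar minutes by modal category with a fixed tie-break
priority (in_vehicle > indoor > other — ties go to the rarer, more
exposure-relevant class), mean position/speed/altitude. Minutes are
inner-joined with the 1-min concentration series; unmatched rows are
counted, never imputed.

**Traffic covariates** (`pbpah.spatial_traffic`). Kernel traffic density
at a point uses the quadratic (Silverman) kernel
`K(d) = 3/(πr²)(1 − (d/r)²)²` with segments discretized at ≤ 5 m; each
sub-segment carries mass AADT × length(km), giving vehicles/day·km per
km². Length-weighted AADT averages AADT over road length clipped to a
500-m buffer (`Σ AADT·len / Σ len`); a buffer containing no road yields
"missing", not zero.

**Quality assurance** (`pbpah.qa_filters`). Three order-stable,
idempotent filters: (1) runs of consecutive "in_vehicle" minutes whose
bounding-circle radius is < 100 m **and** mean speed < 10 km/h are
vehicle-cluster suspects (likely parked/indoors with a warm GPS) and are
removed; (2) indoor minutes strictly above 1000 ng/m³ are removed as
source-contaminated (cooking/smoking); (3) days with < 360 valid minutes
are dropped entirely. Every removed minute is accounted for in a report.

**Aggregation** (`pbpah.aggregation`). Temporal flags use half-open
intervals: weekday Mon–Fri; daytime [06:00, 19:00); rush [06:00, 08:00) ∪
[16:00, 19:00); timezone-naive timestamps are rejected. Geometric
summaries floor values at the 1 ng/m³ detection limit before taking logs
(count reported); skewness is the adjusted Fisher–Pearson coefficient,
0 by convention for zero-variance samples.

**Model fitting** (`pbpah.exposure_models`). The recipe at each level:
correlation screen (drop |r| < 0.10 with the outcome; flag covariate
pairs with |r| ≥ 0.8), LASSO path over standardized survivors
(least-angle regression), unpenalized OLS refit of every active set along
the path, and selection by minimum AIC (LASSO-shrunken coefficients carry
no standard errors, hence the refit). Reported per term: β, SE, p,
sequential (Type-I) partial R² in path entry order (increments sum
exactly to R²; an order-dependent accounting, stated as such), and VIF
(`1/(1 − R²_j)`). The daily mixed model is REML via `statsmodels MixedLM`
with a *diagonal* random intercept + random slope covariance (a `free`
pattern); when the slope variance collapses the model falls back to
intercept-only with a recorded warning. Rank-deficient designs raise.

## Synthetic-data generator

No field data ship with the package; `pbpah.synthetic_data` provides two
generators.

**Trajectory cohort** (`simulate_cohort`): a grid road network with
uniform AADT in [5 000, 80 000]; 28 subjects with home/work anchors; 3–10
sampling days each with a 900-min waking day of 15-s fixes. Per-minute
schedules target 91.3% indoor / 4.5% in-vehicle / 4.2% other with a
lognormal day-level multiplier (CV ≈ 1) so day-to-day variation matches
the reported spread. In-vehicle motion follows the nearest road polyline
(ping-pong at ends); GPS noise is Gaussian (SD 5 m) truncated at ±3σ so
the invariant "vehicle fixes lie within 4σ of a road" holds
deterministically. Concentrations are lognormal per true category with
geometric means 1.9 / 46.8 / 3.2 ng/m³, clipped to the instrument range
[1, 4000].

**Tabular generative twins** (`simulate_regression_table`): analysis
tables drawn directly from published coefficient tables (intercept, βs,
residual SD) with predictors drawn from their published moments. These
drive the parameter-recovery experiments in `pbpah.recovery` and
`scripts/acceptance.py`: tables are redrawn, refit, and replicate-mean
estimates compared with the generative values.

## Parameter choices (package decisions)

| Parameter | Default | Rationale |
|---|---|---|
| per-category GSDs | 1.5 / 2.0 / 2.0 | not published; small enough that detection-limit flooring shifts the indoor GM < 2%, so configured GMs are recoverable |
| classifier thresholds | 8 / 2 km/h, 50 m, window 5 | separate driving from walking from dwelling at GPS noise levels |
| tie-break priority | in_vehicle > indoor > other | deterministic minutes; favours the rare high-exposure class |
| kernel bandwidth / discretization | 300 m / ≤ 5 m | quadrature error < 1e-6 relative |
| AADT buffer | 500 m, clipped lengths | whole-segment weighting is also available |
| QA thresholds | 100 m & 10 km/h; 1000 ng/m³ (strict >); 360 min | study protocol values |
| mixed-model covariance | diagonal (independent RI + RS) | the correlation is not estimable at these group sizes |
| selection criterion | AIC (min); R² available | R² is monotone along the path and favours the largest set |
| recovery replicates | 200 / 100 / 500 / 500 | Monte-Carlo SE small against reporting precision within the runtime budget |

Determinism: all randomness descends from one integer seed through
`numpy.random.SeedSequence.spawn`; same seed ⇒ identical output across
runs and platforms.

## Numerical and statistical notes

- Replicates whose random design is degenerate (e.g. a Bernoulli(0.179)
  column drawn all-zero in a 28-row table, probability ≈ 0.4%) are
  skipped and counted in recovery experiments: OLS is undefined there and
  the models condition on an estimable design.
- REML via L-BFGS can raise a singular-matrix error when a variance
  component collapses to zero (the score inverts the profiled information
  matrix); the fit falls back to derivative-free Powell optimization.
- Timestamps are serialized to CSV in UTC and restored to the study
  timezone (`America/Los_Angeles`) on read; mixed DST offsets do not
  round-trip reliably otherwise.
- AIC model selection retains a covariate roughly when its |t| exceeds
  √2, so weak true effects (population t ≈ 2.5) are dropped in ~15% of
  replicates; selection-consistency checks are calibrated to that, not to
  perfect recovery.

## Limitations

- The generator is a behavioural cartoon: fixed anchors, grid roads,
  stationary schedules; no transit modes, GPS dropouts, multipath urban
  noise, or seasonal concentration trends (weather covariates are
  generated independent of concentration).
- Concentrations depend only on the true time-activity category, not on
  traffic proximity, so cohort-level regressions are dominated by the
  in-vehicle fraction; the recovery experiments use the tabular twins
  instead, where every published coefficient is the truth.
- One projection zone is implemented (UTM 11N on GRS80); parameters for
  other zones can be supplied via `UtmZone`.
- The microenvironment generator fixes near-balanced category counts
  (25/25/24 of n = 74); only the total n is published.
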