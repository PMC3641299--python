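# Methods

## Spatial model

All layers share one carrier: a georeferenced 2D grid with an explicit
nodata mask. Coordinates are metres; the origin is the top-left *corner*;
rows grow southward; the center of cell (i, j) is at
`(origin_x + (j+½)·cell, origin_y − (i+½)·cell)`. Every distance in the
package (nearest-feature distances, kriging lags, variogram bins) is
center-to-center under this single convention, which prevents half-pixel
drift between stages. The default cell size is 250 m, matching 16-day
vegetation-index composites at that resolution. The CRS is carried as an
opaque label and checked for equality only; reprojection is out of scope.
Zone (district) rasterization assigns a cell to the polygon containing its
center; presence rasterization marks any cell whose rectangle intersects a
feature. Grids are stored as single-band float64 GeoTIFFs so that the
write→read round trip is exact.

## Stage 1 — vegetation-trend detection

**Quality screening.** Per-observation quality flags map to fit weights;
the default follows the MODIS pixel-reliability convention (0 → 1.0,
1 → 0.5, 2 and 3 → 0.0, configurable). Weight 0 means "missing".

**Gap filling.** Missing observations are linearly interpolated in time
between the flanking valid observations. Leading/trailing gaps take the
nearest valid value — a deliberate hold, never extrapolation, because
series endpoints have the highest leverage on the fitted trend. Filled
values re-enter the smoother at the minimum positive weight (0.1) so they
constrain the fit as weakly as possible. Pixels with fewer than two valid
observations are flagged unusable and masked downstream.

**Adaptive Savitzky–Golay smoothing.** Each point is replaced by the value,
at its own position, of a weighted least-squares polynomial fitted over a
moving window (half-window 4 composites ≈ 64 days, order 2 by default;
windows truncate at the series ends). Then an upper-envelope adaptation
runs for a configurable number of iterations (default 2): points below the
current fit have their weights multiplied by a decay factor (default 0.5)
and the fit repeats. The rationale is that atmospheric contamination biases
vegetation indices downward, so the upper envelope is the better estimate
of the true canopy signal. Windows that are degenerate (all weights zero,
or fewer positive-weight points than polynomial coefficients) fall back to
an unweighted fit with a warning. The solver is a batched normal-equation
solve across all pixels per time step with a 1e-12 Tikhonov guard; for an
order-2 fit the guard perturbs reproduced polynomials by ≪ 1e-9.

A note on the envelope: down-weighting a below-fit point provably raises
the fit *at that point*, and the package tests that monotonicity there.
It does not hold pointwise across the whole window — a quadratic refitted
without a low observation can dip slightly elsewhere (a seesaw effect) —
so no such global claim is made or tested.

**Seasonal summation.** ΣNDVI per pixel and year is the plain sum of
smoothed values of composites whose *start date* falls inside the season
window (default April 1 – October 31 inclusive). Start-date membership is
the one unambiguous rule for 16-day composites that straddle month
boundaries.

**Trend fit and classes.** Per pixel, ordinary least squares of ΣNDVI on
the year index 0…k−1 (so the intercept is the level in the first year);
the slope's t statistic has k−2 degrees of freedom. Classes: slope < 0 with
two-sided p ≤ 0.05 → high negative trend; p ≤ 0.10 → medium; other negative
slopes → low; slope ≥ 0 → other (positive trends are out of scope). The
thresholds are the 95 % and 90 % confidence levels read as two-sided p
ceilings, equivalently one-tail bounds 0.025 and 0.05 on the negative
slope; slope exactly 0 is "other" because the negative classes are defined
on the negative slope. A perfectly linear pixel gets p = 0 (t = ±∞
sentinel); an exactly constant pixel gets slope 0, p = 1. High+medium
merge into the binary degraded-land outcome.

**Diagnostics.** Endpoint sensitivity recomputes the class map without the
first and without the last year and reports the percent of identically
classified cells (overall agreement). Zonal areal statistics count cells
per district and class, convert to hectares (cell² / 10⁴) and percent of
the district's unmasked area, and add a medium+high column and a TOTAL row
that sums districts — the convention used for degraded-land area totals.

## Stage 2 — logistic risk model

**Sampling.** One uniformly random unmasked cell per non-overlapping 3×3
window (750 m at 250 m cells). This thins short-range spatial dependence;
given the factor fields, outcomes are conditionally independent Bernoulli
draws, so likelihood-based standard errors remain valid. The sample splits
50/50 into calibration and validation.

**Multicollinearity.** VIFⱼ = 1/(1−R²ⱼ) from regressing predictor j on the
retained others (with intercept); the largest VIF is dropped while any
exceeds 5. Exact collinearity counts as infinite VIF and is removed first —
in practice this removes one of the four soil-fertility dummies, which are
complementary by construction.

**Fit.** Maximum likelihood via Newton iterations (equivalent to IRLS for
the logistic link), tolerance 1e-8 on the score, 100-iteration cap;
standard errors from the inverse observed information. Non-convergence is
surfaced as a warning (the usual symptom of complete separation).
Backward stepwise removal drops the predictor with the largest Wald
p > 0.05 and refits until all survive; α is configurable and α = 1
reproduces the full fit. The full and stepwise models are compared on
validation AUC with a correlated-AUC z test (DeLong placement-variance
estimator); when the test is significant the higher-AUC model is kept,
otherwise the more parsimonious one. A paired-bootstrap cross-check of
that test lives in the test suite.

**Validation.** AUC is the rank-based (Mann–Whitney) estimate with ties
counted one half — exactly the mean over positive×negative pairs. PCP is
the percent of validation cells classified correctly at probability 0.5.
The goodness-of-fit χ² is the likelihood-ratio statistic of the fitted
model against intercept-only, df = number of slope terms
(Hosmer–Lemeshow is deliberately not implemented).

**Reporting and risk map.** Coefficients are reported with
odds % = 100·(e^β − 1) and significance stars (*p<0.1, **p<0.05, ***p<0.01,
****p<0.001). The fitted probability surface is ranked descending (ties
broken by row-major cell order) and cut at ranks round(c·N/10), so the ten
classes are equal-count within one cell and class 1 holds the top decile of
risk.

## Groundwater interpolation

Well observations (multi-year means; duplicated locations averaged) are
interpolated by ordinary kriging with a spherical semivariogram
γ(h) = nugget + psill·(1.5h/r − 0.5(h/r)³) capped at the sill beyond the
range. The empirical semivariogram is binned method-of-moments (15
equal-width lags to half the domain diagonal by default) and the model is
fitted by least squares weighted by √(pair count), parameters constrained
non-negative. Prediction solves the ordinary-kriging system (semivariogram
form with the unbiasedness constraint; weights sum to 1) over the 16
nearest wells; γ(0) = 0, so a nugget-0 model interpolates the wells
exactly. Ordinary rather than simple kriging because the field mean is
unknown; the moving neighborhood bounds cost. An all-constant well set
degenerates to the flat model (nugget = psill = 0, range = max distance).

## Factor layers

Distances are exact Euclidean distance transforms of presence grids
(center-to-center, metres). Line density is clipped polyline length per
cell rectangle over cell area (m/m²); the integral of density·area equals
total in-grid length. Land-use flags from an annual class series:
*no change* requires one identical class for ≥ 6 consecutive years;
*uncultivated* requires a fallow code in ≥ 6 years **in total** (the
consecutive reading is available behind a switch, since "abandoned for six
years" is ambiguous between the two). District water-use variability is
the mean absolute consecutive-year difference of the district's annual
series, spread over the district's cells — one fixed reading of "average
delta of water use", isolated in a single function. Terrain slope is
consumed as a ready raster. The soil-fertility class grid expands into
four 0/1 dummies. Layers are assembled in a canonical 18-name order with
binary/continuous kind tags, validated for alignment and binary range, and
masked by the union of layer masks.

## Synthetic study region

The generator emulates the statistical structure of an irrigated lowland,
not its geography:

- **Continuous fields** (groundwater table 0.8–2.5 m, salinity 0.5–4 g/l,
  slope 0–3 %, a fertility field cut into four classes at the 10/40/80 %
  quantiles) are Gaussian-smoothed white noise (radius 6 cells) min-max
  rescaled — cheap, seedable, and spatially autocorrelated enough to
  exercise the 3×3 sampling rationale, but *not* a calibrated
  geostatistical model of any real aquifer.
- **Infrastructure** is random gently-bent polylines, points and boxes;
  distances and densities are then derived with the real factor-map
  operations.
- **Outcome.** Degradation labels are Bernoulli draws from the logistic
  model with β₀ = −3.55 and effects 1.46 (groundwater table), 0.71
  (uncultivated), 0.40 (fertility class I), 0.25 (slope), 0.23 (salinity) —
  the reference study's headline coefficients, so parameter-recovery tests
  run at realistic effect sizes. With the field scales above this yields a
  prevalence near 0.45, higher than the ~0.14 of the reference region; the
  package treats prevalence as a consequence, not a target.
- **NDVI cube.** Each year repeats 23 fixed calendar composite slots (the
  16-day positions of a 365-day year, so season membership is identical
  across leap years). The seasonal template is a quadratic bump spanning
  the growing season plus a 0.12 baseline; amplitudes decline linearly for
  degraded cells (ΣNDVI slope drawn uniformly from −0.4 to −0.1 per year)
  and stay flat elsewhere. Because the bump is a single quadratic across
  the window of every in-season composite, an order-2 Savitzky–Golay fit
  reproduces in-season values *exactly*, so at zero noise the planted
  ΣNDVI slopes survive the full pre-processing chain to machine precision —
  that is what makes the stage-1 closed loop a sharp test. Observation
  noise is iid Gaussian (σ = 0.02); 15 % of observations are flagged
  half-weight and 5 % missing.
- **Wells** sample the noise-free groundwater surfaces at jittered uniform
  locations (500 per surface by default).

What passing tests on this scenario do **not** show: robustness to real
phenology (multi-modal seasons, double cropping), cloud-correlated gap
structure, sensor drift, registration error, or label noise beyond the
stage-1 misclassification the pipeline itself produces (~5 % of
non-degraded cells enter the degraded class at the designed type-I level,
which mildly attenuates stage-2 coefficients).

## Problem sizes and numerical choices

The default scenario is 120×120 cells × 11 years × 23 composites; the full
two-stage pipeline runs in well under a minute on one CPU, and the test
suite uses 40–60-cell grids where the full size adds nothing. The
acceptance script uses the default size for the closed loop, n = 4,056 ×
100 replicates for coverage, and a 100×100 null cube for the type-I check.
Ties in the decile map break by row-major order; the VIF screen treats
R² ≥ 1 − 1e-12 as exact collinearity; kriging systems are solved densely
per neighborhood (singular systems are retried after averaging coincident
wells, then reported); the variogram fit starts from half the first-bin
semivariance and half the domain. All randomness flows from a single seed
per run, recorded in every manifest.

## Known limitations

- One projection; no reprojection or resampling.
- No alternative smoothers (double-logistic, Whittaker) or robust trend
  estimators (Theil–Sen, Mann–Kendall); positive trends are not analysed.
- The logistic model ignores residual spatial autocorrelation beyond the
  block-sampling mitigation (no autologistic/GEE variant).
- Universal kriging, anisotropy and variogram cross-validation are out of
  scope; groundwater is treated as temporally static.
- The 18-layer factor vocabulary is fixed; new predictors require a code
  change, not just configuration.
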