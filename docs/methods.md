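# Methods

This note documents the statistical and numerical choices behind
`pneumorisk`: what each stage assumes, which parameters matter, what the
synthetic-data generator does and does not emulate, and where the design
was genuinely open.

## Count regression

The response is the number of under-five pneumonia cases per district in
one reporting year; the model is the standard Poisson GLM with log link,

    y_i ~ Poisson(mu_i),   ln mu_i = beta_0 + sum_j beta_j x_ij.

The Poisson assumption implies mean–variance equality; no dispersion
parameter is estimated, and quasi-Poisson or negative-binomial extensions
are deliberately out of scope. With only 18 districts, the deviance
goodness-of-fit test is the practical overdispersion check: a deviance far
above the chi-square critical value signals either real covariate effects
or extra-Poisson variation, and the package reports it without attempting
to disentangle the two.

**Fitting.** Iteratively reweighted least squares (Fisher scoring on the
working response z = eta + (y − mu)/mu with weights mu), initialized at
beta_0 = ln(mean(y) + 0.5) and zero slopes. Each Newton step is halved (up
to 50 times) whenever it would increase the deviance, which makes the
deviance sequence monotone non-increasing and the iteration robust on
small, poorly conditioned tables. Convergence is a relative deviance change
below 1e-8, default cap 100 iterations; non-convergence raises an error
that carries the last iterate. Standard errors come from the inverse Fisher
information at the optimum; the log-likelihood (and hence the AIC =
−2ℓ + 2p) includes the ln y! term, matching the usual GLM convention.

**Multicollinearity screen.** VIF_j = 1/(1 − R²_j) from an
ordinary-least-squares regression of predictor j on all other predictors
plus an intercept; tolerance is 1/VIF. Backward elimination removes the
single worst predictor with VIF > 10 and recomputes, until all survive.
Ties on the maximum VIF are broken toward the later column (a fixed,
documented rule; any deterministic choice would do). Note that with 18
rows and 13 predictors each auxiliary regression spends 13 of 17 degrees
of freedom, so the screen is intentionally aggressive at study scale —
exactly the regime in which three climate/staffing covariates fail it.

**Inference conventions.** Significance is assessed at two-sided
alpha = 0.1 (equivalently one-sided 0.05). The normal critical value is
1.6449; the package reports it at 3 dp (1.645) and, in summary tables, at
2 dp via half-up rounding of the 3-dp value (1.65). That two-stage
convention matters: plain 2-dp rounding of 1.6449 would print 1.64, whereas
published epidemiological tables conventionally print 1.65. The deviance
test uses df = number of non-intercept predictors by default (overridable)
and the upper-alpha chi-square quantile (15.987 for alpha = 0.1, df = 10).

**Runs test.** The residual autocorrelation diagnostic is the
Wald–Wolfowitz runs test applied to the signs of the response residuals
y − mu in input row order; exact zeros are dropped. The normal
approximation with a 0.5 continuity correction is used; against exhaustive
enumeration at n+ = n− = 4 it is accurate to better than 0.1, which is
adequate for a diagnostic read as "large p = no evidence of pattern".
Response residuals (not Pearson or deviance) and row order are conventions;
neither materially changes the sign sequence at study scale.

## Spatial stages

**IDW interpolation.** Each raster cell center receives
sum(w_i Z_i)/sum(w_i) with w_i = d_i^(−p). The exponent is not dictated by
the method and defaults to p = 2, the near-universal GIS default;
`IdwConfig` exposes it along with an optional k-nearest-stations cut.
Distances are planar degrees: the study region spans ~1.5° on the equator,
where the lon/lat anisotropy is under 0.1%, far below the uncertainty of
the interpolation itself. A cell within 1e-9° of a station receives the
station value exactly (exact-interpolator contract); coincident stations
with conflicting values are rejected. Positive weights make every
interpolated value a convex combination of station values, hence bounded
by their range — a property the tests enforce.

**Zonal aggregation.** Rasters are averaged to districts over the cell
centers strictly inside each polygon (nodata excluded). The cell-center
rule is the simplest deterministic choice; area-weighted aggregation is a
non-goal. Default grid resolution is 0.01°, fine enough that every
district in an 18-cell Voronoi tessellation of the study bbox captures
hundreds of cells; a polygon capturing none is an error naming the
polygon. Grid convention: lower-left origin, row 0 southernmost, cell
centers at origin + (index + 0.5)·cellsize; the ASCII-grid writer emits
rows north-first per the ESRI format, at 8 significant digits.

**Natural breaks.** Fisher's O(k·n²) dynamic program over the distinct
sorted values (weighted by multiplicity) minimizes the total within-class
sum of squared deviations; working on distinct values guarantees identical
values always share a class, and the DP is globally optimal — verified
against exhaustive enumeration of all contiguous partitions for n ≤ 12.
Boundaries are reported as [data minimum, class maxima…]; classes are
upper-inclusive, the lowest class closed at both ends, so a value equal to
an interior boundary falls in the lower class. When the optimal lowest
class is the singleton minimum, b0 = b1 by construction and is accepted.
Values outside the break range clamp to the extreme classes with a
warning. The GVF diagnostic (1 − SSD_within/SSD_total) is provided; k = 3
is used throughout the pipeline, any k ≥ 2 is supported.

## Vulnerability scoring

Seven factors enter the composite score: population density, rainfall,
exclusive breastfeeding, malnutrition, healthy homes, under-five service
coverage and health-facility count. Risk-direction factors map
low/medium/high to 1/2/3; protective factors (exclusive breastfeeding,
healthy homes, service coverage) are reverse-scored 3/2/1. Reverse scoring
is the only reading under which a high total consistently means high
vulnerability — a district with *low* breastfeeding coverage must
contribute a *high* score — and it is the default, with a switch to
disable it. Totals therefore live in [7, 21]. The default classification
uses fixed thresholds (high > 14, medium 12–14, low < 12); a
natural-breaks mode re-runs Jenks with k = 3 on the totals and labels the
ascending classes low/medium/high, falling back to the fixed rule (with a
warning) when fewer than three distinct totals exist. In fixed mode the
level is monotone in every factor score. The map stage emits a GeoJSON
FeatureCollection with district id, total and level per feature, plus the
level counts, which always partition the districts.

## Synthetic data generator

No per-district raw table is published, so the generator emulates the
study conditions and is itself first-class, tested code.

- **Geometry.** 18 districts as Voronoi cells of seeded uniform points in
  the study bounding box (100.28–101.35°E, 1.23–2.75°N), bounded by
  mirroring the seeds across the box edges, so the cells exactly tile the
  box. Irregular, interior-disjoint, deterministic — an adequate stand-in
  for administrative polygons, with no claim to real boundaries.
- **Covariates.** Each of the 13 covariates is drawn from a truncated
  normal on its published [min, max] — the simplest family consistent with
  all four published summaries. Crucially the underlying location/scale are
  *moment-matched*: plugging the published mean/SD in directly would bias
  the realized mean wherever the bounds are asymmetric (population density
  would come out near 80 instead of 69.78). The location is solved by root
  finding so the truncated mean equals the published mean exactly at every
  candidate scale, and the scale then minimizes the SD mismatch. For
  heavily truncated rows (malnutrition: mean 0.056, SD 0.081 on [0, 0.31])
  the published SD is infeasible within the family and the closest
  achievable SD is used; the mean always matches. An SD = 0 spec yields a
  point mass.
- **Counts.** mu_i = exp(beta_0 + sum beta_j x_ij) with the published
  slope estimates. The published intercept (8.306) belongs to an
  unrecoverable covariate scaling of the original fit — applied to
  covariates on the published scales it produces astronomical means — so
  the generator keeps the slope structure and solves the intercept (in log
  space) so that the mean of mu over districts equals a target burden,
  default 1954/18 ≈ 108.6 cases per district, the study region's reported
  annual total. A calibrated linear predictor above 700 (exp overflow)
  raises an error naming the district.
- **Stations.** One station per district at a uniform random interior
  point (rejection sampling), values drawn from the field's moment-matched
  truncated normal. The pipeline interpolates the rainfall field and
  replaces the tabular rainfall covariate by the zonal means, so the
  climate covariate genuinely flows through the IDW stage.
- **Collinear triple.** Optionally (`collinear_triple`, on in the default
  pipeline configuration) air temperature, air humidity and health-worker
  count are rebuilt as near-linear combinations of three disjoint surviving
  covariates each, with noise set so the construction's R² is 0.94: each
  rebuilt column's VIF is then ≈ 1/(1 − 0.94) ≈ 17 while the sources stay
  near 6, so backward elimination removes exactly the triple — the
  multicollinearity structure the screen is meant to catch. Rebuilt columns
  are rescaled to the published mean/SD but not re-truncated, since a hard
  clip would bend the linear dependence being constructed.

**What the generator does not emulate:** spatial autocorrelation between
neighbouring districts, correlation between covariates (beyond the
constructed triple), reporting/detection artifacts in the counts, real
administrative boundaries, and real climate surfaces. Passing tests
therefore demonstrate that the *methods* are implemented correctly and
recover known structure — not that the original study's specific
coefficient values would be reproduced from the real (unpublished) data.

## Problem sizes and determinism

Oracle comparisons run at sizes where exhaustive enumeration is exact and
fast: Jenks on 100 instances with n ≤ 12, runs-test enumeration at
n+ = n− = 4, IDW on a 20×20 grid with 10 stations. Parameter recovery and
Wald-interval coverage use 50 simulated datasets of 2,000 districts —
large enough for near-nominal coverage (observed ≈ 0.95 against the ≥ 0.90
requirement), small enough to run in seconds. The full pipeline runs at
the study scale of 18 districts on a 0.01° grid. All randomness descends
from a single root seed through `numpy.random.SeedSequence` spawning, one
child per stage, so every artifact is a pure function of (config, seed);
the run log records the effective configuration, versions and timings
(the only non-deterministic artifact, and the only one excluded from the
byte-identity check).

## Known limitations

- n = 18 with 10+ predictors is a fragile regression setting; standard
  errors are honest only conditional on the Poisson model, and the VIF
  screen's removals vary between simulated draws (the study-scale screen is
  noisy by nature; the constructed triple is removed reliably at n ≥ ~200).
- The deviance test needs mu large enough for its chi-square calibration;
  at the default burden (~109 cases/district) this is comfortably met.
- IDW with one station per district produces smooth bull's-eye surfaces;
  zonal means are then close to the district's own station value. This is
  the method's behaviour, not a defect, but it limits how much the
  interpolation stage can change the analysis at 18 stations.
- Fixed risk thresholds (>14 / 12–14 / <12) assume exactly seven 3-point
  factors; with a different factor set the natural-breaks mode is the
  appropriate choice.
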