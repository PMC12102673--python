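# pneumorisk

District-level risk mapping for under-five pneumonia.

Childhood pneumonia remains a leading cause of under-five mortality in
Indonesia, and its burden varies strongly between administrative districts.
`pneumorisk` implements, as a tested and reusable pipeline, the standard
district-level analysis used to prioritize interventions: a Poisson count
regression linking per-district case counts to demographic, climatic,
socioeconomic and health-infrastructure covariates, combined with a
GIS-style workflow — inverse-distance-weighted (IDW) interpolation of
station climate data, Fisher–Jenks natural-breaks classification of each
risk factor, and a composite Likert-score overlay that classifies districts
into high / medium / low vulnerability zones. It is written for
epidemiologists and health-GIS analysts who want the whole chain, from raw
tables to a choropleth-ready GeoJSON map, reproducible from a single seed.

## The model

Case counts are modelled as a Poisson log-linear regression (GLM with log
link):

    y_i ~ Poisson(mu_i),        ln mu_i = beta_0 + sum_j beta_j x_ij

fitted by iteratively reweighted least squares, with standard errors from
the inverse Fisher information. Around the fit:

- **Multicollinearity screen** — VIF_j = 1/(1 − R²_j), where R²_j comes from
  regressing predictor j on all the others; predictors with VIF > 10 are
  removed by backward elimination before fitting.
- **Partial tests** — Wald z = beta_j / se(beta_j) against the two-sided 10%
  normal critical value (1.645, reported as 1.65).
- **Simultaneous test** — the deviance D = 2 Σ[y ln(y/mu) − (y − mu)]
  against the upper-10% chi-square quantile (15.987 at 10 df).
- **Autocorrelation diagnostic** — a Wald–Wolfowitz runs test on the signs
  of the response residuals.

The spatial side interpolates station values with IDW weights w_i = d_i^−p
(p = 2 by default, an exact interpolator), aggregates the raster to
districts by cell-center zonal means, partitions each factor into three
classes by the globally optimal Fisher–Jenks dynamic program, scores the
classes 1/2/3 on a Likert scale (protective factors reverse-scored), sums
the seven significant factors per district and classifies the totals into
risk zones (high > 14, medium 12–14, low < 12).

Because the original per-district table is not published, the package ships
a first-class synthetic-data generator that reproduces the study
conditions: 18 Voronoi "districts", 13 covariates drawn from
moment-matched truncated normals that reproduce the published min / max /
mean / SD summaries, one climate station per district, and counts simulated
from the published slope estimates with an intercept calibrated to the
published overall burden (1,954 cases over 18 districts).

## Worked example

```python
from pneumorisk import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(output_dir="run", seed=42))
print(result.fit.summary())
print("VIF removed:", result.vif_removed)
print("risk level counts:", result.counts)
```

prints (abridged):

```
Poisson log-linear regression of district case counts
====================================================================
variable                      estimate   std_error   z_score  sig
--------------------------------------------------------------------
β0                            -15.2051      1.8434    -8.249  *
rainfall                        0.0042      0.0007     6.435  *
malnutrition                    5.3899      0.6112     8.818  *
healthy ... (10 predictors in total)
health_facilities               0.0703      0.0071     9.957  *
--------------------------------------------------------------------
Deviance: 16.25    AIC: 153.07
Z_table(0.05): 1.65    chi2(0.1:10): 15.987
Significance alpha = 0.1
VIF removed: ['air_humidity', 'health_workers', 'healthy_home']
risk level counts: {'low': 5, 'medium': 10, 'high': 3}
```

Three covariates fail the VIF < 10 screen on this simulated draw and are
eliminated, leaving 10 predictors; rainfall, malnutrition and
health-facility density come out as significant risk factors (starred rows:
|z| > 1.65), and the composite Likert overlay splits the 18 districts into
3 high-, 10 medium- and 5 low-risk zones. All artifacts (district table,
polygons, stations, rainfall raster, VIF report, fit summary, per-factor
breaks, scores, the vulnerability GeoJSON and a run log) are written to
`run/`.

The same chain is available from the shell:

```bash
pneumorisk pipeline --seed 42 --out run
pneumorisk simulate --seed 3 --out sim
pneumorisk fit --districts sim/districts.csv --out fit.csv
pneumorisk interpolate --stations sim/stations.csv --out rain.asc
```

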