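# heatptb

A reusable, tested pipeline for estimating total and natural direct effects
of warm-season apparent temperature on daily preterm-birth counts, with:

- **Exposure preparation** — the quadratic apparent-temperature (AT) formula
  `AT = -2.653 + 0.994*T + 0.0153*Td²`, secondary-station backfill, 2-day lag
  means, log transforms for skewed covariates, and May–September restriction.
- **Multiple imputation** — chained-equations imputation of missing pollutant
  values (ozone, PM10, NO2) from lag 0–2 meteorology and pollutants; three
  imputations after two burn-in sweeps by default.
- **Total effects** — Poisson time-series regression of daily counts with
  cubic B-splines for day-of-year and year, a centred-linear + hinge AT
  term, covariates (solar radiation, wind, ln precipitation), relative risks
  at the p95-vs-p50 exposure contrast, attributable fractions
  `(1 − 1/RR) × 100%`, and day-resampling percentile bootstrap CIs.
- **Mediation** — natural direct effects via inverse odds weighting: a
  linear exposure model on the pollutant mediators yields per-day weights
  (two schemes: the literal `1/exp(Â/σ²)` form and a normal density-ratio
  form), used in a weighted refit without pollutants. Indirect = total −
  direct, pooled over imputations; the bootstrap re-runs both stages.
- **Additive effect modification** — RERI (`RR11 − RR10 − RR01 + 1`) per
  maternal indicator from a negative-binomial (Poisson at the dispersion
  boundary) model on date × stratum expanded counts, with cluster (by date)
  bootstrap CIs.
- **Case-crossover sensitivity** — time-stratified referent selection
  (2-week/3-week/month strata, weekday matched) and a count-weighted
  conditional-logistic odds ratio at the same exposure contrast.
- **Synthetic scenarios** — a seeded generator (`heatptb.synthetic`) for
  weather, AT-driven pollutants with injectable missingness, and stratified
  Poisson/negative-binomial birth counts with known true RRs, AFs and
  calibrated interaction targets, so every estimator can be checked against
  ground truth.

## Command line

```bash
heatptb simulate --scenario mediation --seed 1 --out-dir scratch/sim
heatptb prepare --primary scratch/sim/weather.csv \
                --pollutants scratch/sim/pollutants.csv \
                --out scratch/series.csv
heatptb impute --series scratch/series.csv --m 3 --seed 1 --out-dir scratch/imp
heatptb fit-total --series scratch/series.csv --counts scratch/counts.csv \
                  --doy-knots 5 --n-boot 500 --seed 1 --out scratch/table3.csv
heatptb mediate --series scratch/series.csv --counts scratch/counts.csv \
                --scheme density_ratio --out scratch/mediation.json
heatptb interactions --births scratch/sim/births.csv \
                     --series scratch/series.csv --out scratch/table4.csv
heatptb case-crossover --series scratch/series.csv \
                       --counts scratch/counts.csv --stratum 2w \
                       --out scratch/cc.csv
heatptb run-all --scenario mediation --seed 1 --out-dir scratch/results
```

`run-all` executes every stage from one config (YAML via `--config`) and
writes demographics, exposure-summary, effect (with a knot-sensitivity
sweep), mediation-decomposition, RERI and case-crossover tables, plus an
exposure–response curve CSV. All seeds are explicit; rerunning an identical
config reproduces every output byte for byte.

## Notes

- AF uses `(1 − 1/RR) × 100`; the reciprocal variant `1/(1 − RR) × 100` is
  available behind `attributable_fraction(..., literal=True)` for
  documentation only (it is negative for any RR > 1).
- In the stratum-expanded interaction model there is no at-risk denominator,
  so indicator main effects absorb stratum composition; RERI magnitudes are
  therefore model-scale quantities (the synthetic generator calibrates its
  interaction targets on the same scale), and a modifier with no injected
  interaction has RERI `(RR10−1)(RR01−1)`, which is zero only under a null
  exposure effect.
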