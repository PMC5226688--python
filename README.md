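# histexpo

Historical spatio-temporal prediction of annual-average PM2.5
concentrations (µg/m³) at arbitrary continental-US locations for
1980–2010, for epidemiological exposure assessment.

Dense regulatory PM2.5 monitoring (the FRM network) only exists from 1999,
but many cohorts need residential exposure estimates going back decades.
`histexpo` fits a spatio-temporal model to the monitored years and carries
the temporal signal backwards with proxy data sources, then assigns
residence-weighted long-term averages across participants' address
histories.

## Model

Log annual averages are decomposed as

```
log y(s, t) = mu(s) + beta(s) · f(t) + eps(s, t)
```

* `mu(s)`: spatially varying long-term mean — universal kriging on two
  partial-least-squares (PLS) scores of the geographic covariates, with an
  exponential spatial covariance (range, partial sill, nugget) estimated by
  maximum likelihood;
* `f(t)`: a single temporal trend basis, the first singular vector of the
  site×year matrix of long-series monitoring sites (1999–2010), extended to
  1980–1998 three ways — straight-line extrapolation, a sulfate-network
  proxy trend, or a visibility (visual-range) proxy trend, each affinely
  calibrated to the monitored trend;
* `beta(s)`: a spatially varying coefficient on `f`, regressed on the same
  PLS scores (no spatial covariance in the primary configuration);
* `eps(s, t)`: spatially correlated, temporally independent annual
  residuals, simple-kriged within monitored years and zero before 1999.

Evaluation uses site-held-out 5-fold cross-validation and external
validation with the MSE-based R² (`1 − MSE/Var(obs)`), RMSE, and
calibration lines of predictions on observations. Annual input data pass
the standard inclusion rules first: at least two-thirds of scheduled
sampling dates valid and no 45-day run of consecutive missing days;
visibility records additionally drop fog/dust/precipitation days and are
truncated at 16.093 km.

See `docs/methods.md` for the full account.

## Worked example

No real monitoring data ships with the package; the `simulate` module
generates synthetic monitoring worlds with the model's structure (a dense
primary network observed only 1999–2010, a historical validation network,
sulfate- and visibility-like proxies, and retained truth fields).

```python
import numpy as np
import histexpo as hx

world = hx.world_a()                       # canonical 400-site fixture world
years = list(range(1999, 2011))
mat = hx.site_year_matrix(world.annual["primary"], years=years, min_years=6)
f = hx.estimate_trend_svd(mat)             # monitored-years trend
trend = hx.extend_trend_linear(years, f, range(1980, 1999))

model = hx.SpatioTemporalModel(random_state=1).fit(
    world.annual["primary"], world.sites, world.covariates, trend)

cv = hx.cross_validate(world.annual["primary"], world.sites,
                       world.covariates, trend, k=5, seed=1,
                       model_params={"random_state": 1})
print(f"CV R2 {cv.overall['r2']:.3f}  RMSE {cv.overall['rmse']:.2f} ug/m3 "
      f"slope {cv.overall['slope']:.2f}")

ext = hx.external_validate(model, world.annual["validation"], world.sites,
                           world.covariates)
print(f"external (1990-1998, 70 sites) R2 {ext.overall['r2']:.3f}")

hist = np.arange(1980, 1999)
r = np.corrcoef(trend.value(hist),
                world.truth["f_star"].loc[1980:1998])[0, 1]
print(f"historical trend correlation with truth {r:.3f}")
```

prints

```
CV R2 0.827  RMSE 2.35 ug/m3 slope 0.81
external (1990-1998, 70 sites) R2 0.812
historical trend correlation with truth 1.000
```

The cross-validated R² of 0.827 means held-out-site annual predictions
explain ~83 % of the between-site-year variance about the identity line;
the slope below 1 reflects the usual attenuation of kriged predictions.
External validation on the pre-1999 network — sites and years never seen in
fitting, predicted with zero residual component — is nearly as good, and
the back-extrapolated trend tracks the generating trend essentially
perfectly here because the true pre-1999 decline is linear.

The same operations are available from the shell:

```bash
histexpo simulate --seed 20160624 --out world/
histexpo trend --annual world/annual_primary.csv --approach sulfate \
    --proxy-annual world/annual_sulfate.csv --proxy-start 1987 --out trend.csv
histexpo fit --annual world/annual_primary.csv --sites world/sites.csv \
    --covariates world/covariates.csv --trend trend.csv --out model.json
histexpo predict --model model.json --locations locations.csv \
    --covariates world/covariates.csv --years 1980:2010 --out pred.csv
histexpo exposure --model model.json --residences residences.csv \
    --covariates world/covariates.csv --window 1980-01-01:2000-12-31 \
    --out exposure.csv
```

plus `histexpo crossvalidate`, `histexpo validate-external`, `histexpo qc`
and `histexpo run --config run.yaml` for a checksum-gated, resumable
pipeline.

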