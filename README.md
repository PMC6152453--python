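# cropflux

Chamber CO₂ flux partitioning and spectral models of daily gross ecosystem
production (GEP) for crop canopies.

`cropflux` is for researchers who measure plot-scale CO₂ exchange with closed
dynamic chambers alongside ground radiometry (NDVI/SAVI/PRI bands) and leaf
area index (LAI), and who want to estimate daily GEP from spectral
observations.  It implements the full chain:

1. **Per-closure fluxes** — the OLS slope of the chamber headspace CO₂ trace
   converted to an area flux, F = (ΔC/Δt)·V/(A·M_v), with r² quality control
   (fluxes with r² < 0.8 excluded, near-zero fluxes flagged for review
   instead).
2. **Campaign flux models** — per field day, a Lloyd–Taylor respiration fit
   R_eco(T) = R_ref·exp(E0·(1/(T_ref−T0) − 1/(T−T0))) to opaque-chamber
   fluxes and a rectangular-hyperbola light response
   GEP(PAR) = α·PAR·GP_max/(α·PAR + GP_max) to GEP = NEP + R_eco from
   transparent-chamber fluxes.
3. **Reconstruction** — linear interpolation of (R_ref, E0, α, GP_max)
   between campaigns, evaluation on continuous 30-min PAR/temperature
   drivers, NEP = GEP − R_eco, and sunrise-to-sunset daily sums GEP_d
   (gCO₂-C m⁻² d⁻¹) and daylight-mean PAR_d.
4. **Spectral indices** — NDVI, SAVI, PRI from reflectances or raw
   dual-radiometer readings, plus the wide-dynamic-range transform
   WDRVI = [(α+1)·NDVI + (α−1)]/[(α−1)·NDVI + (α+1)] (α = 0.2) and its
   rescaling sWDRVI = (WDRVI+1)/2.
5. **GEP_d models** — the four linear models GEP_d = a·x + b with
   x ∈ {LAI, VI, VI·PAR_d, VI·LAI}, reported with R², RMSE and
   NRMSE = 100·RMSE/range, plus per-crop validation (bias of summed
   predictions) of the pooled general model.
6. **Hysteresis analysis** — a Welch-type two-sample t-test comparing the
   GEP_d-vs-VI slope between the vegetative and reproductive phases of the
   season (split at the LAI maximum).  Multiplying a saturating greenness
   index by LAI gives a predictor with the same seasonality as GEP_d and
   reduces this phase hysteresis.

A synthetic-season generator (`cropflux.synthetic`) produces drivers,
phenology, reflectance and chamber closures with known ground truth, so the
whole chain is testable without field data.

## Worked example

```python
import numpy as np
from cropflux import FluxPartitionModel, chamber
from cropflux.synthetic import SeasonConfig, generate_season, generate_closures
from cropflux.regression import GEPRegression, ModelSpec
from cropflux.phases import hysteresis_table

cfg = SeasonConfig.winter_cereal_hysteresis(seed=1)
truth = generate_season(cfg)

rng = np.random.default_rng(42)
records, dates = [], []
for day in truth.campaign_days:
    for cl in generate_closures(day, truth, cfg, rng=rng):
        records.append(chamber.process_closure(cl))
        dates.append(day)
records = chamber.qc_filter(records)

results = FluxPartitionModel(records, truth.drivers, latitude=cfg.latitude,
                             record_dates=dates).fit()
print(results.summary())
```

```
Flux partitioning: plot winter_wheat
  campaigns fitted : 13 (skipped 0)
  respiration temp : t_soil

  date        Rref    E0      alpha    GPmax
  2012-03-05    2.79   308.6   0.0500    30.1
  ...
  2012-05-28    3.12   308.6   0.0500    66.0
  ...
  2012-07-27    2.70   308.6   0.0500    21.5

  daily records    : 156
  GEP_d max        : 18.85 gCO2-C m-2 d-1
  PAR_d mean       : 910 umol m-2 s-1
```

GP_max tracks the green canopy (peaking with LAI in late May) and the
season's maximum daily GEP is ≈ 19 gCO₂-C m⁻² d⁻¹, typical of a productive
winter cereal.  Fitting the NDVI·LAI spectral model to every fourth day and
testing the phase hysteresis:

```python
daily = truth.daily.iloc[::4].reset_index(drop=True)
fit = GEPRegression.from_dataframe(daily, ModelSpec(4, "NDVI"),
                                   dataset_label="winter cereal").fit()
print(fit.summary())
print(hysteresis_table(daily).round(3).to_string(index=False))
```

```
GEP_d ~ NDVI*LAI [winter cereal]
  GEP_d = 6.29 * NDVI*LAI + -0.62
  n = 39   R2 = 0.96   RMSE = 0.78 gCO2-C m-2 d-1   NRMSE = 6.24 %   p = 1.4e-27

predictor         crop split_date  slope_veg  slope_rep      t     df     p  significant
     NDVI winter_wheat 2012-05-27    166.248     83.595  3.519 30.338 0.001         True
 NDVI*LAI winter_wheat 2012-05-27      6.048      6.836 -2.233 24.511 0.035         True
```

NDVI alone has very different GEP_d slopes in the two phases (166 vs 84,
p ≈ 0.001) because the dense winter canopy keeps NDVI near its asymptote
through green-up; the NDVI·LAI product brings the slopes to 6.0 vs 6.8 and
shrinks |t| from 3.5 to 2.2.

The same chain is available from the shell:

```sh
cropflux run --seed 1 --out-dir demo_run
```

which writes every intermediate table (closures, fluxes, campaign
parameters, 30-min series, daily table with indices, model table,
validation, hysteresis tests) plus a markdown report into `demo_run/`.

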