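# Methods

## Chamber fluxes

A closure is a 120 s (transparent, NEP) or 180 s (opaque, R_eco) deployment
of a closed dynamic chamber.  The flux is computed from the OLS slope of the
headspace CO₂ mixing-ratio trace,

    F = (ΔC/Δt) · V / (A · M_v),

with chamber volume V (default 0.296 m³), collar area A (default 0.5625 m²,
a 0.75 × 0.75 m frame) and the ideal-gas molar volume
M_v = R·T/p evaluated at the closure-mean chamber air temperature and
pressure.  Conventions:

* Signs: NEP and GEP are uptake-positive, R_eco is release-positive, and
  NEP = GEP − R_eco.  A transparent closure's raw slope is negated.
* The first 10 s of each trace are discarded by default for headspace
  mixing transients (configurable; the field protocol is silent on this).
* Closure air temperature is the mean over the closure.
* QC: r² of the slope fit below 0.8 excludes the flux, except that
  |F| ≤ 0.5 µmol m⁻² s⁻¹ is flagged `near_zero_review` and retained by
  default — a genuinely tiny flux yields a flat trace whose r² is low for
  lack of signal, not lack of quality.  This codifies as a magnitude rule
  what is otherwise a manual inspection step.  A zero-variance trace is
  assigned slope 0 and r² = 0 (flagged), keeping QC deterministic.

## Campaign flux models

Per campaign day (and plot) two sub-models are fitted by nonlinear least
squares (`scipy.optimize.curve_fit`):

* Lloyd–Taylor respiration
  R_eco(T) = R_ref · exp(E0 · (1/(T_ref − T0) − 1/(T − T0))) with the
  model's canonical constants T_ref = 283.15 K and T0 = 227.13 K.  Bounds:
  R_ref ∈ (0, 50] µmol m⁻² s⁻¹, E0 ∈ [50, 450] K.  When the campaign's
  temperature span is below 2 °C the sensitivity is unidentifiable and E0
  is fixed at 308.56 K (the model's classic estimate), leaving a
  closed-form R_ref.  At least 4 usable respiration fluxes are required.
* Michaelis–Menten (rectangular hyperbola) light response
  GEP(PAR) = α·PAR·GP_max/(α·PAR + GP_max), fitted to
  GEP = NEP + R_eco(T) where R_eco comes from the fitted respiration model
  at each NEP closure's temperature.  Bounds α ∈ (0, 0.3],
  GP_max ∈ (0, 120] µmol m⁻² s⁻¹; three fixed starts
  (α, GP_max) ∈ {(0.02, 20), (0.05, 40), (0.10, 80)}, smallest SSE wins,
  ties broken toward the smaller GP_max.  Requires ≥ 4 points spanning
  ≥ 200 µmol m⁻² s⁻¹ of PAR; an all-zero GEP campaign is flagged
  degenerate.

The respiration temperature driver is soil temperature when available, else
air temperature (configurable); the measurement protocol does not name one.

## Reconstruction and daily aggregation

The four parameters are interpolated linearly in time between campaign days
anchored at 12:00 local solar time (campaigns run sunrise to late
afternoon, so noon is their natural centre), and held constant before the
first and after the last campaign.  On the 30-min driver grid,
GEP = light response of PAR, R_eco = Lloyd–Taylor of temperature,
NEP = GEP − R_eco; GEP is exactly 0 wherever PAR = 0.

Daily GEP is the sum of the 30-min GEP values between sunrise and sunset,
converted with 1800 s per step and 12.011 × 10⁻⁶ gC µmol⁻¹:
GEP_d [gCO₂-C m⁻² d⁻¹].  PAR_d is the arithmetic mean of 30-min PAR over
the same window.  The window comes from a standard NOAA solar-geometry
approximation (zenith 90.833°, local solar time; |latitude| < 66.5°), or
alternatively from the first/last driver step with PAR above
1 µmol m⁻² s⁻¹.  Missing steps inside the window raise an error rather
than biasing the sum.

## Spectral indices

NDVI = (ρ850 − ρ670)/(ρ850 + ρ670), SAVI the soil-adjusted variant with
L = 0.5 (the canonical soil factor), PRI = (ρ570 − ρ531)/(ρ570 + ρ531).
Raw dual-radiometer mode applies
VI = (Z·R1_r·Y − R2_r·X)/(Z·R1_r·Y + R2_r·X) with the ratio sensitivity Z
applied per band pair.  WDRVI is computed from NDVI through the Möbius
transform with weight α = 0.2 (strictly increasing, fixed point at 1) and
sWDRVI = (WDRVI + 1)/2 rescales it to [0, 1].

## GEP_d regression and validation

Simple OLS (statsmodels) of GEP_d on one of LAI, VI, VI·PAR_d or VI·LAI.
Statistics follow the conventions needed to make RMSE/NRMSE pairs
self-consistent: RMSE uses divisor n (population form, configurable) and
NRMSE = 100·RMSE/(max − min) of the observed GEP_d in the fitted dataset —
back-computing range = RMSE/NRMSE·100 reproduces the observed GEP_d ranges,
whereas mean-normalization does not.  Rows missing a required component
(LAI for models 1 and 4, PAR_d for model 3, the VI for 2–4) are dropped
pairwise per model, which is why n varies between rows of the model table.
PRI enters model 2 only; its LAI products are not formed.  Validation of a
pooled general model regresses predicted on observed GEP_d per crop and
reports the relative bias of the summed predictions, flagged above 25 %.

## Phase analysis

Each crop-year splits into vegetative and reproductive phases at the date
of maximum LAI (default; maximum GEP_d or a manual date are alternatives).
The GEP_d-vs-predictor slope is fitted per phase and compared with a
Welch-type two-sample t-test on slopes:
t = (a₁ − a₂)/√(SE₁² + SE₂²) with Welch–Satterthwaite degrees of freedom
built from the per-fit residual dof (nᵢ − 2); significance at p < 0.05.
Daily light-use efficiency is defined as incident-light LUE,
LUE = GEP_d/(PAR_d · daylength · 10⁻⁶) in gC per mol photons.

## Synthetic seasons

The generator emulates the study conditions of a central-European crop
site (52.43° N):

* **Drivers.**  PAR is a half-sinusoid between solar sunrise and sunset
  with a seasonal noon amplitude (1700 µmol m⁻² s⁻¹ at the in-season
  maximum, following noon solar elevation), damped by a per-day beta-
  distributed cloudiness factor (`weather_noise`, default 0.35); clear-sky
  daylight-mean PAR_d then peaks near 1050 µmol m⁻² s⁻¹ with a seasonal
  mean in the high hundreds.  Temperature is a seasonal plus diurnal
  sinusoid (annual mean 8.5 °C, seasonal amplitude 10 °C peaking late July,
  diurnal amplitude 5 °C peaking mid-afternoon); soil temperature is a
  damped copy.
* **Phenology.**  Total LAI rises logistically from `lai_start` (winter
  crops are already green when the analyzed period opens) to exactly
  `lai_max` at `lai_peak_doy`, then declines logistically to a plateau
  (senesced canopy persisting at 2–3 m² m⁻² by default).  Green LAI equals
  total LAI before the peak and declines linearly at
  `green_fraction_decline` per day after it.
* **Reflectance.**  NDVI saturates with canopy greenness,
  NDVI = NDVI_∞ − (NDVI_∞ − NDVI_soil)·exp(−k_ext·g).  The greenness
  argument is g = greenLAI + β·(LAI − greenLAI) with β the
  `senescent_greenness` carried by yellowing leaves; NDVI as a function of
  green LAI alone would force GEP and NDVI onto a single curve in both
  phases and no hysteresis could exist.  ρ850 is held fixed and ρ670 solved
  from NDVI; the photochemical bands sit at a constant PRI level (−0.19).
  Band noise is additive gaussian, truncated at zero.
* **Flux truth.**  GP_max = 20·greenLAI µmol m⁻² s⁻¹ (peak canopy GP_max
  ≈ 66 for LAI 3.3, giving maximum GEP_d ≈ 19–20 gCO₂-C m⁻² d⁻¹), α = 0.05,
  R_ref = 2.5 µmol m⁻² s⁻¹ plus a 25 % green-biomass term, E0 = 308.56 K.
  The true parameter trajectories are piecewise linear between campaign
  days (every 12 days, anchored at 12:00) and closures on a campaign day
  draw their true fluxes from that day's anchor values.  This mirrors the
  interpolation the estimation procedure itself assumes, so the zero-noise
  round trip is exact and recovery tests isolate estimation error from
  structural mismatch; it does not represent sub-daily physiological
  drift.
* **Closures.**  5–12 transparent/opaque closure pairs per campaign day
  (scaling with daylength), 1 Hz, spread from half an hour after sunrise to
  two hours before sunset; each trace drifts at
  slope = F_true·A·M_v/V plus gaussian concentration noise.  The gas
  analyzer's sampling rate is not documented for the field system; 1 Hz is
  assumed.

Two named scenarios fix the phase-analysis conditions:
`SeasonConfig.winter_cereal_hysteresis()` (dense canopy at season start,
k_ext = 1.8, plateau 2.0, β = 0.1, slow green decline, mild weather noise)
reliably exhibits the vegetative/reproductive NDVI hysteresis that the
NDVI·LAI product reduces; `SeasonConfig.hysteresis_free()` sets
`green_fraction_decline = 0` so greenness never detaches from green LAI.
Note that even hysteresis-free seasons do not have exactly equal
phase slopes for any curved VI–GEP relation (spring and late-summer
radiation differ at matched LAI), so the slope-test calibration is
checked on simulated phases with equal true slopes built on a season's
NDVI design.

## What the synthetic tests do and do not show

Passing round-trip and recovery tests demonstrate that the estimation
chain is implemented correctly and is numerically stable at realistic
noise levels (0.3 ppm trace noise leaves median parameter errors well
under 10 %).  They do not validate the flux models against real canopies:
the generator contains no drought response (a dry year is emulated only by
lowering `lai_max`), no water-vapour dilution or pressure artefacts in the
chamber, no radiative-transfer realism in reflectance (band values are any
pair consistent with the target NDVI), and no footprint or advection
effects.

## Numerical choices

* Problem sizes: the test suite uses a 61-day season for exact round
  trips, 50 replicates for noisy recovery, 1000 replicates for the
  slope-test calibration, and 4–7-day observation cadences for the
  regression and phase analyses — season-scale analyses at the cadence of
  the field campaigns they emulate.
* Zero-variance traces, all-zero GEP campaigns and constant responses are
  defined (flagged) rather than errors; degenerate predictors raise.
* Linear interpolation uses `numpy.interp` (hold extrapolation); OLS via
  statsmodels; nonlinear fits via bounded trust-region least squares.
* Seeds: every stochastic component takes an explicit seed or Generator;
  equal seeds give bit-identical tables.

## Known limitations

* Parameter uncertainty is not propagated to GEP_d (no confidence
  intervals on daily sums).
* Per-plot parameter interpolation only; per-crop aggregation across
  replicate plots is left to the caller.
* The supplementary-table loader expects a CSV export; proprietary
  statistics-package formats are not read directly.
* Polar sites (|latitude| ≥ 66.5°) are unsupported by the solar window.
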