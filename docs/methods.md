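# Methods

This note records the models, conventions and numerical choices behind
`thermoresp`, and what the synthetic-data tests do and do not establish
about real data.

## The measurement model

A bird rests in a ventilated chamber (volume V, incurrent flow FR of dry,
CO2-free air) while cabinet air temperature is stepped upward. The
chamber is treated as a single well-mixed compartment, so excurrent O2
fraction and water vapor pressure approach each new steady state as a
first-order process with time constant V/FR; 95% equilibration takes
t95 = (V/FR)·ln 20 (3.1 min at 2500 ml/min and 3.9 min at 2000 ml/min
through the default 2.6 L chamber). A multiplexer records the incurrent
(baseline) stream for 10 min at the start and end of each run; analyzer
drift is modelled as linear in time per analyzer, which is exactly the
component identifiable from two bracketing baselines — the correction
maps both baseline means onto their reference values and is exact for
affine drift and idempotent. Analyzer latency is a fixed per-analyzer
time shift (defaults 12 s for O2, 20 s for WVP), undone before windowing.

Per-step resting values are the means of the most stable 5-min window of
the O2 trace, where "stability" is minimum sample variance over a sliding
300 s window with 1 s stride (earliest window on ties); all channels are
averaged over the same window. The search never enters the first t95
seconds of a step: recording a step's value only once the chamber has
re-equilibrated is part of the protocol, and windows that straddle the
transient would otherwise leak the previous step's gas into the mean.
Steps with less than 5 min of usable chamber data are excluded and
logged, as are steps cut short by the welfare truncation (core Tb ≥ 45
°C, after which no chamber sample is emitted).

## Conversions

* VO2 (ml/min) = FR·(FiO2 − FeO2)/(1 − FiO2), for a dry CO2-free stream.
* Thermal equivalent of oxygen: 16 + 5.164·RQ J/ml. RQ = 0.71
  (post-absorptive) when the bird has fasted more than 62 min — the mean
  digesta retention time of a ~31 g passerine — else 0.80; the threshold
  is exclusive. Metabolic power (W) = VO2 · (J/ml) / 60.
* EWL (g/hr) = water vapor density × flow in m³/hr, with density
  ρ = e/(R_v·T) evaluated **at chamber air temperature**. Whether a real
  logging chain uses chamber or analyzer-cell temperature here is a
  convention; the chamber-temperature choice reproduces the documented
  8.2 g/m³ humidity ceiling (saturation at dew point 9.5 °C in 42.2 °C
  air) and is used consistently by the simulator and the reduction, so
  the round trip is exact. Saturation vapor pressure uses Tetens'
  formula (bookkeeping only).
* EHL (W) = EWL · 2.406 J/mg; cooling efficiency = EHL/MHP with MHP the
  resting metabolic power. Evaporative scope = max EWL / min EWL per
  bird.

## Breakpoint estimation

Each trait's air-temperature inflection is the knot ψ of the continuous
hinge model y = β0 + β1·Ta + β2·(Ta − ψ)+ fitted to all birds pooled.
SSE(ψ) is profiled on a candidate grid (default 0.01 °C) restricted so at
least three distinct Ta values lie on each side, then refined by
golden-section search within one grid cell; the profiled SSE is computed
from cumulative sums (exact normal equations per candidate), so the grid
scan is a true brute-force minimization. The hinge nests the straight
line (β2 = 0), so SSE(hinge) ≤ SSE(line) always. Pooling ignores the
repeated-measures structure; dependence is restored for the interval by a
case-resampling bootstrap over birds (percentile 2.5/97.5, B ≥ 200,
seeded). The interval construction is a documented stand-in — bootstrap
replicates refit on a 0.05 °C grid for speed, which bounds the CI
resolution at that level.

## Mixed models and selection

Observations above each trait's estimated inflection are modelled with a
per-bird random intercept and fixed effects drawn from {Ta, Mb, Ta:Mb}
respecting marginality — five candidates from intercept-only to the full
interaction model. All fits are maximum likelihood (not REML) so
log-likelihoods are comparable across fixed-effect structures; the
reported estimates come from the same ML fit (no REML refit of the top
model, a deliberate single-fit consistency choice). Parameter count k =
fixed effects + random-intercept variance + residual variance (k = 4 for
{Ta}). Ranking uses AICc = −2logL + 2k + 2k(k+1)/(n−k−1); models with
ΔAICc < 8 form the retained set; Akaike weights are computed over all
converged candidates and a top weight above 0.90 is labelled
overwhelming. Confidence intervals are Wald (±1.96 SE).

With five candidates and these penalties, a generator with no true mass
effect caps the achievable top weight near 0.72 even when the superfluous
terms add nothing: weights near 1 require the competing models to fit
*worse* than their penalty, not merely no better. Selection tables should
be read with that ceiling in mind.

Influence is measured per bird: D_i = (β̂ − β̂₍₋ᵢ₎)ᵀ Cov(β̂)⁻¹ (β̂ −
β̂₍₋ᵢ₎)/p over the fixed effects, by leave-one-bird-out refits. Note a
random-intercept model absorbs constant per-bird offsets, so only birds
whose *response shape* deviates (e.g. an aberrant thermal slope) drive D
above the conventional threshold of 1. Any such bird triggers a robust
refit: marginal residuals are winsorized at 1.345 robust standard
deviations (1.4826 × MAD, so the scale ignores the outliers themselves)
and the winsorized response refitted by ML, iterating until the fixed
effects stabilize. Without outliers this converges to within ~1% of the
plain ML estimates; its standard errors are approximate (post-winsorized
ML), which is acceptable for its role as a fallback estimator.

## Thermoregulatory polygon

Dry heat balance requires M ≤ C·(Tb − Ta) with conductance C (W/°C).
Between a metabolic floor at BMR and a ceiling at mult·BMR this bounds a
polygon in (Ta, M) space whose right edge is the dissipation line; the
passive limit at a given activity level is Ta_max = Tb − mult·BMR/C, and
the floor and ceiling being parallel, a finite polygon needs a cold-side
cutoff (default −40 °C, display only). **The shipped default conductance
0.1167 W/°C is not a measurement**: it is back-computed from a 22 °C
passive limit at 4 × 0.563 W and Tb 41.3 °C, so checks against those
numbers are consistency checks, not validation. Evaporative heat loss is
deliberately excluded from the boundary — the framework describes
*passive* (dry) balance. A related published observation is left
unreconciled on purpose: active birds hitting the dry limit at 22 °C sit
1.4 °C below "11.2 °C under the resting EWL inflection" (34.6 − 11.2 =
23.4 °C); both numbers are surfaced as given.

## The synthetic generator: what it emulates and what it does not

Trait responses are flat below a trait-specific inflection and linear
above it, with defaults describing a ~31 g cold-specialist passerine:
Tb 41.3 °C inflecting at 32.6 °C (slope 0.299 °C/°C), resting metabolic
rate 0.588 W at 29.8 °C (0.014 W/°C), EWL 0.315 g/hr at 34.6 °C (0.068
g/hr/°C); body mass ~N(31.0, 2.1²) g; fasting times ~N(90, 25²) min so
roughly one bird in eight gets RQ 0.80. Between-bird variation enters as
per-trait random intercepts and within-bird variation as per-step
residuals. Published studies report only between-bird SDs of step means,
so the split is a calibrated judgment fixed in advance: Tb 0.15/0.15 °C
(intercept/residual; combining to the ~0.2 °C reported at thermoneutrality),
RMR 0.08/0.05 W (~0.105 reported), EWL 0.05/0.04 g/hr. The ramp default
is 25 → 43 °C in 2 °C, 15-min steps after 30 min habituation, with 10-min
baselines; 1 Hz noise SDs are 5×10⁻⁶ (O2 fraction), 0.002 kPa (WVP), 0.05
°C (Ta, Tb); drift slopes are drawn per session (SD 10⁻⁴ O2/hr, 0.01
kPa/hr). The scrubbed incurrent stream carries a residual 0.06 kPa WVP
(dew point ≈ −24 °C) — a strictly positive baseline is also what keeps a
negatively drifting WVP analyzer identifiable against the zero floor. The
subcutaneous sensor reads core Tb − 0.2 °C with 0.1 °C noise; a panting
annotation is emitted at ψ_EWL − 1.4 °C.

Deliberately not emulated: behavioral restlessness and escape (exclusions
enter only via the 5-min rule), CO2 (scrubbed in this configuration),
heteroscedastic residuals at extreme heat, mass effects on any trait, and
per-bird inflection variation (ψ SD defaults to 0, matching the pooled
estimator's assumption). Passing recovery tests therefore show that the
estimators are calibrated *under these conditions*; they do not certify
performance under strong heteroscedasticity or real behavioral artifacts.

## Numerical and design notes

* Seeding: every stochastic stage takes an explicit seed; per-session
  seeds derive from the study seed, and identical configurations produce
  byte-identical reports.
* Stable-window ties resolve to the earliest window; tie detection uses a
  relative 10⁻⁹ tolerance on the window variance.
* The termination rule evaluates the simulated (noisy) core Tb at 1 Hz;
  the triggering tick is the last chamber sample, and the closing
  baseline is still recorded.
* The "0 < O2 fraction < 0.21" physical bound applies to the gas signal;
  a positively drifting analyzer may *read* marginally above the
  incurrent fraction, as real drifting analyzers do.
* Mixed-model fits fall back from the default optimizer to Powell/CG and
  treat non-finite log-likelihoods as failures; a random-intercept
  variance pinned at zero is kept but flagged, and such fits reduce to
  OLS.
* Mb in the candidate models is the pre-measurement mass.
* Parameter-recovery studies in the test suite use 200 simulated studies
  of 42 birds (the suite's heaviest job, ~5 min); bootstrap-coverage and
  contamination checks run at reduced replicate counts sized for the
  suite, with thresholds set for those counts.

## Known limitations

* The RMR inflection is weakly identified at realistic noise: with slope
  0.014 W/°C against ~0.09 W pooled SD, even an idealized point-level
  estimator shows ~0.5 °C median error, and the pooled fit's low-side
  errors attenuate the above-inflection slope. Interval estimates for
  RMR inflections should be taken seriously; point estimates should not
  be over-read.
* The robust refit reports approximate (non-sandwich) standard errors.
* The cluster bootstrap assumes birds are the only dependence unit; no
  year/session stratification is modelled.
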