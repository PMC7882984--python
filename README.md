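# thermoresp

Heat-tolerance analysis of ramped-temperature, flow-through respirometry
data from small endotherms — built around the study design used for
cold-specialist passerines (a ~31 g Arctic songbird): birds sit in a
ventilated metabolic chamber while air temperature (*T*a) is stepped
upward, and body temperature (*T*b), oxygen consumption, and water vapor
pressure are logged at 1 Hz until the bird shows heat stress or reaches a
welfare cutoff (*T*b ≥ 45 °C).

The package is for thermal ecophysiologists who want the full chain from
raw multiplexed traces to heat-tolerance statistics as tested, scriptable
code:

1. **synth** — a seeded generator of complete raw sessions with known
   ground truth (first-order chamber washout, analyzer drift and lag,
   baseline/chamber multiplexing, per-bird random intercepts, per-step
   residuals), so every downstream stage is testable without any data
   download.
2. **traces** — reduction of raw traces to per-step resting values: lag
   alignment, linear drift correction against bracketing baselines,
   washout exclusion, and the "most stable 5-min window" rule on the O2
   trace.
3. **physio** — standard respirometry conversions: VO2 = FR·(FiO2 −
   FeO2)/(1 − FiO2); metabolic power via the thermal equivalent of oxygen
   (16 + 5.164·RQ J/ml, RQ chosen by fasting time); EWL from water vapor
   density × flow; evaporative heat loss at 2.406 J/mg; cooling efficiency
   EHL/MHP.
4. **segmented** — the *T*a inflection point of each trait by continuous
   two-segment ("hinge") regression, y = β0 + β1·Ta + β2·max(0, Ta − ψ),
   profiled over a 0.01 °C grid with golden-section refinement and a
   cluster (per-bird) bootstrap CI for ψ.
5. **models** — random-intercept linear mixed models fitted by ML above
   each inflection; AICc model selection over the marginality-respecting
   subsets of Ta × Mb ("dredge"), Akaike weights, grouped Cook's distance
   by leave-one-bird-out, and an automatic Huber robust refit when any
   bird has D > 1.
6. **polygon** — the thermoregulatory polygon: with dry thermal
   conductance C, the passive heat-balance boundary M = C·(Tb − Ta) gives
   the warmest environment an animal working at a given multiple of BMR
   can tolerate without evaporative cooling, Ta_max = Tb − mult·BMR/C.

Everything hangs off two statsmodels-style pairs:
`SegmentedRegression(...).fit()` → `SegmentedResults`, and
`HeatResponseModel(points, trait).fit()` → `HeatResponseResults` (with
`summary()` tables), plus a `PipelineConfig`/`run_pipeline` orchestrator
and a `thermoresp` CLI (`simulate`, `reduce`, `breakpoint`, `analyze`,
`polygon`, `run`, `washout`).

## Worked example

Simulate a 42-bird study at the package defaults, reduce it, and analyze
body temperature:

```python
import thermoresp as tr
from thermoresp import pipeline as pl

cfg = pl.PipelineConfig(n_birds=42, seed=7)
points, _ = pl.reduce_sessions(pl.simulate_study(cfg), cfg)
res = tr.HeatResponseModel(points, "Tb_C").fit(grid=0.01, boot=1000, seed=7)
print(res.summary())
```

```
Two-segment regression (continuous hinge)
---------------------------------------------
n_obs                   420
breakpoint psi       32.462 degC
psi 95% CI       [32.29, 32.64] degC (cluster bootstrap)
slope below psi     -0.0077 per degC
slope above psi      0.2963 per degC
intercept           41.4929
SSE (hinge)          17.493
SSE (one line)       90.641

Model selection: Tb_C  (n=252, birds=42, ML + AICc)
          terms  k   loglik     aicc  delta_aicc  weight
        Ta + Mb  5   97.903 -185.562       0.000   0.524
             Ta  4   96.178 -184.193       1.369   0.264
Ta + Mb + Ta:Mb  6   98.050 -183.758       1.804   0.212
              1  3 -365.555  737.208     922.770   0.000
             Mb  4 -365.332  738.826     924.389   0.000
top-model weight 0.524

Estimates from top model (ML): Ta + Mb
  Intercept    32.3744 +- 0.4089  95% CI [31.5730, 33.1758]  t = 79.18
  Ta            0.2963 +- 0.0026  95% CI [0.2913, 0.3014]  t = 115.18
  Mb           -0.0246 +- 0.0130  95% CI [-0.0501, 0.0008]  t = -1.90
max grouped Cook's distance: 0.096
```

The generator's true body-temperature response is flat at 41.3 °C below an
inflection at 32.6 °C and rises 0.299 °C per °C above it: the fitted
breakpoint (32.46 °C, CI 32.3–32.6) and above-inflection slope (0.296 ±
0.003) recover both, and the spurious mass term that sneaks into this
seed's top model (Mb, t = −1.9, ΔAICc 1.4 to the Ta-only model) is a
faithful picture of how much model-selection noise ~250 observations
carry. The selection table also shows why a weight of 0.524 — not 0.95 —
is the typical level of support for the true structure in a five-candidate
set.

Project the passive heat-balance limit of an active bird:

```python
poly = tr.ThermoPolygon(bmr_W=0.563, conductance_W_per_C=0.1167,
                        tb_C=41.3, activity_multiplier=4.0)
print(f"passive limit at 4x BMR: {poly.ta_max_passive_C:.1f} degC")
```

```
passive limit at 4x BMR: 22.0 degC
```

A bird producing four times its basal 0.563 W can shed that heat dry only
below 22 °C: activity brings the onset of obligatory evaporative cooling
far below the resting EWL inflection. Note the shipped default
conductance (0.1167 W/°C) is back-computed from exactly these numbers,
not independently measured — supply your own C whenever you have one.

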