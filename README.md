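# lekscape

Spatially heterogeneous analysis of male greater sage-grouse lek attendance
versus oil and gas well-pad density.

Male sage-grouse gather each spring at traditional display sites (leks);
the peak male count at a lek indexes the local breeding population. Energy
development fragments sagebrush habitat, but its effect on lek attendance
is not uniform in space: the same development density can depress some leks
and leave others untouched. `lekscape` implements, as a reusable and tested
pipeline, the analysis style used to study this question in Wyoming-scale
lek databases:

1. **Lagged multi-scale density covariates.** For each lek, the density of
   active well pads (pads/km², closed disc, count/(πr²)) within 0.5, 1, 2,
   5 and 10 km, evaluated 1, 3, 5 and 10 years before the attendance-trend
   window, after filtering pads that were never drilled (permit-only) or
   had ceased activity (dry hole / dormant with an end date).
2. **Periodicity-corrected trend responses.** Lek counts cycle over 3–5
   year horizons. Counts are mapped to empirical proportions
   p = (c + ½)/(c_max + 1) of the lek maximum, logit-transformed, smoothed
   over years by LOWESS (local-linear tricube) with the span chosen on a
   grid by corrected AIC, and back-transformed. OLS slopes of the smoothed
   series over the most recent 3, 5 and 10 years give the trend responses
   (males/lek/year), alongside the adjusted final-year count and a binary
   increasing/decreasing indicator.
3. **Geographically weighted regression (GWR).** At each lek *i*,
   β̂(u_i) = (XᵀW_i X)⁻¹XᵀW_i y with kernel weights
   w_ij = (1 − (d_ij/b)²)² (bisquare, adaptive neighbour-count bandwidth by
   default) or exp(−½(d_ij/b)²) (gaussian). Model complexity is tr(S) and
   2tr(S) − tr(SᵀS); model support is the small-sample corrected AIC; the
   improvement over global OLS is an approximate F test. A binomial family
   (geographically weighted logistic) handles the binary response.
4. **Monte Carlo nonstationarity tests.** Per covariate, the variance of
   the local coefficients is compared with its distribution under random
   permutation of the lek coordinates (same bandwidth), giving
   p = (1 + #{perm ≥ obs})/(1 + n_perm).
5. **Significance mapping.** Leks whose local *t* exceeds the two-sided
   critical value are interpolated into continuous surfaces by inverse
   distance weighting (ESRI ASCII grid output) and summarised per region.
6. **Functional responses and thresholds.** OLS lines of attendance change
   on pad density per (radius, lag) region, forecasts at current densities,
   and the sustainable development density: the largest density whose
   predicted change still clears a floor.

Because the underlying agency databases are not public, the package ships a
first-class synthetic-data generator that emulates the study system —
periodic counts, compounding multi-year drilling intensification, dispersed
or Thomas-clustered pad configurations, and a known spatially varying
(mostly negative) lagged response — so every stage can be validated against
ground truth.

## Worked example

```python
from lekscape import pipeline
from lekscape.types import AnalysisConfig

cfg = AnalysisConfig(seed=42, n_permutations=99)
study = pipeline.simulate_study(cfg, n_leks=150)
result = pipeline.run_pipeline(cfg, study.leks, study.pads, final_year=2011)

s = result.summary
print(f"eligible leks:        {s['n_eligible_leks']}")
print(f"best response:        {s['best_response']}")
print(f"adaptive bandwidth:   {s['bandwidth']:.0f} neighbours")
print(f"GWR vs OLS:           F = {s['anova_F']:.2f}, P = {s['anova_p']:.4f}")
line = result.lines[(2.0, 1)]
print(f"response line (2 km, lag 1): change = {line.slope:.2f} x density + {line.intercept:.2f}")
th = result.thresholds[(2.0, 1)]
print(f"sustainable density (2 km): {th.density:.3f} pads/km^2 (~{th.pad_count:.1f} pads)")
```

prints

```
eligible leks:        150
best response:        trend10
adaptive bandwidth:   55 neighbours
GWR vs OLS:           F = 3.16, P = 0.0000
response line (2 km, lag 1): change = -3.68 x density + 0.24
sustainable density (2 km): 0.065 pads/km^2 (~0.8 pads)
```

The simulated truth puts a slope of −4 (males/lek/year per pads/km²) on the
2-km density west of the study-area midline and 0 east of it. The F test
rejects a spatially constant model (P < 0.001): local coefficients vary far
more than a global regression allows. The fitted functional response at
2 km is declining, and the threshold says attendance stops declining only
below ≈0.065 pads/km² within 2 km — about one pad on the 12.6 km² disc.
Pseudo-R² values are reported but, as with all GWR pseudo-R², are not
bounded by [0, 1] and are only comparable across responses with similar
scale and variance; the pipeline therefore ranks only the LOWESS trend
responses by it.

The same analysis is available from the shell:

```sh
lekscape simulate --seed 42 --n-leks 150 --out-dir sim
lekscape run-all --leks sim/leks.csv --pads sim/pads.csv \
    --final-year 2011 --out-dir results
```

which writes `responses.csv`, `densities.csv`, per-lek GWR results (CSV and
GeoJSON), IDW surfaces (`.asc`) and `model_summary.json`.

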