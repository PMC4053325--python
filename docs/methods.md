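# Methods

This note records the models, the numerical choices, and the limits of what
the test suite demonstrates.

## Study design the pipeline encodes

The unit of analysis is the lek-year: the peak number of males counted at a
communal display site in one spring. Leks enter the analysis only with
enough survey coverage to support 3-, 5- and 10-year trend regressions:
surveyed in all of the last 3 years, in ≥4 of the last 5, and in ≥6 of the
last 10 including the first year of the decade. All three conditions are
required; the filter is idempotent and parameterised by the final year so
any decade works. A surveyed-inactive year is an observed zero. An
"occupied" management flag (males present at least once in the most recent
10 years) is derived but never used as a model response.

Disturbance is summarised as active-well-pad density around each lek:
count of active pads on the **closed** disc of radius r divided by the full
disc area πr² (pads/km²), with no edge correction — the standard GIS
point-density convention. Ties at exactly r are included because the
closed-disc rule is deterministic and matches count/area semantics. A pad
is active in year t when its interval covers t, except that permit-only
pads that were never drilled (class `AP`, no start year) and pads whose
activity ceased (status `DH`/`DR` with an end date) never count. Densities
are evaluated at lagged reference years: lag ℓ means "pads active ℓ years
before the start of the attendance-trend window". Lags are first-class
configuration and reference years are derived from them, because published
year lists and lag lists for this design are not mutually consistent; the
same reasoning applies to density/pad-count equivalences, so
`count_to_density`/`density_to_count` expose the literal count/(πr²)
conversion and nothing else is assumed.

## Periodicity correction and trend responses

Lek counts cycle with a multi-year period, so a short-window regression on
raw counts confounds cycle with trend. The correction chain is:

1. empirical proportions p_t = (c_t + ½)/(c_max + 1) with c_max the lek's
   own maximum — the half-count offset keeps the logit finite at 0 and at
   the maximum;
2. logit transform z_t = log(p_t/(1 − p_t));
3. LOWESS smoothing of z on year;
4. inverse transform back to the count scale, clipped at 0.

The smoother is local-linear with tricube weights, written as an explicit
linear operator S (so fitted = S·y) with the classical window convention
r = max(2, ⌊span·n⌋). With robustness iterations off this is exactly
classical LOWESS; the implementation is verified bit-for-bit against an
independent LOWESS routine. When a small span collapses the tricube
support onto the focal point, the minimum-norm solve interpolates the
focal value — also the classical behaviour.

The span is selected from the grid {0.3, 0.4, …, 1.0} by corrected AIC,
AICc = n·ln(RSS/n) + 2kn/(n − k − 1) with k = tr(S), the standard form for
linear smoothers. Ties break toward the smaller span. If a span fits the
series perfectly *as a genuine smoother* (RSS ≈ 0 with tr(S) ≤ n − 2, e.g.
constant or straight-line data) the smallest such span is taken;
degenerate interpolating windows do not qualify. Fewer than 5 observed
years falls back to the maximal span with a warning.

Unsurveyed years inside the decade are filled by evaluating the smooth
there, because windowed regressions need a value for every year of the
window. Trend responses are OLS slopes of the adjusted series over the
last 3, 5 and 10 years (males/lek/year); the adjusted final-year count and
a binary indicator (1 if the full-decade trend slope is positive, 0
otherwise — an exactly flat slope counts as not increasing) complete the
response set.

Whether the historical workflow smoothed on the logit scale or the count
scale is ambiguous; both are implemented behind `lowess_fit_scale`, with
`logit` the default. The two differ in their exactness class: the logit
path reproduces logit-linear series exactly, the count path reproduces
count-linear series exactly (the property the linear-recovery tests
exercise). On noiseless linear count data the logit path has a small
smoothing bias because the logit of a line is curved.

## Geographically weighted regression

At focal lek i with coordinates u_i, β̂(u_i) = (XᵀW_iX)⁻¹XᵀW_iy, where
W_i is diagonal with kernel weights. Kernels: gaussian
w = exp(−½(d/b)²) and bisquare w = (1 − (d/b)²)² for d < b else 0; the
self-weight at d = 0 is 1. The default is **adaptive bisquare** — b_i is
the distance to the k-th nearest lek — because leks cluster regionally and
a compact kernel with a neighbour-count bandwidth keeps every local fit
comparably supported. Duplicated coordinates fall back to the nearest
positive distance.

Row i of the smoother matrix is x_iᵀ(XᵀW_iX)⁻¹XᵀW_i, so tr(S) (the hat
trace) and tr(SᵀS) are available exactly; the effective parameter count is
2tr(S) − tr(SᵀS) and the residual degrees of freedom n minus that. Local
standard errors use the model-level error variance
σ̂² = RSS/(n − eff); t = β̂/se. Model support is
AICc = n·ln(RSS/n) + n·ln 2π + n(n + tr(S))/(n − 2 − tr(S)). Pseudo-R² is
1 − RSS/TSS (gaussian) or one minus a deviance ratio (binomial); both are
reported with the caveat that GWR pseudo-R² is unbounded and comparable
only across responses of similar magnitude and variance — the pipeline
ranks only the trend responses by it.

Bandwidth is selected deterministically by a coarse AICc scan bracketing
the minimum followed by golden-section refinement: fixed mode over
[smallest positive pairwise distance, extent diagonal] in metres, adaptive
mode over [p + 2, n] neighbours (snapped to integers, memoised). Any
bandwidth at which some lek is not estimable (rank-deficient local fit) is
excluded. If the refined value loses to the coarse-grid minimum the
profile was not unimodal; the grid minimum is returned with a warning.

The binomial family is geographically weighted logistic regression via
local IRLS (max 25 iterations, tolerance 1e-8); non-convergent leks are
flagged and excluded from maps without aborting the run. For this family
the reported effective parameter count is tr(S) computed from the final
IRLS weights; the two-trace correction would require assembling each
focal's full working-response hat row for little inferential gain.

**Spatial-heterogeneity F test.** With a global OLS comparator,
F = [(RSS_OLS − RSS_GWR)/(eff − p)] / [RSS_GWR/(n − eff)] with approximate
degrees of freedom (eff − p, n − eff); undefined (reported, not raised)
when eff ≤ p.

**Monte Carlo nonstationarity test.** The observed statistic per covariate
is the sample variance over leks of the local coefficient. Each
permutation shuffles the coordinate rows against the fixed (y, X) rows and
refits with the *same* bandwidth — re-selecting per permutation would
multiply cost ~30-fold for a test whose null already conditions on the
observed design; the choice is configurable in principle and flagged here.
p = (1 + #{perm ≥ obs})/(1 + n_perm), so p ∈ (0, 1] and the test is exact
at its nominal level by construction. Local fits that become
rank-deficient under permutation use the minimum-norm solution.

Power of this statistic depends heavily on the spatial spread of the
covariate. On a dense covariate (every lek has nonzero exposure) the step
field is detected with power ≈ 1 at n = 100. On the zero-inflated
densities a sparse landscape produces (most leks have no pad within 2 km),
power is genuinely modest and the model-level F test is the more sensitive
detector — the tests assert exactly that pattern rather than pretending
otherwise.

## Mapping and functional responses

Leks with |t| above the two-sided critical value at α (df = n − eff) are
selected per covariate; per-lek tests are uncorrected by default, matching
the historical per-lek usage, with an optional Benjamini–Hochberg mode.
Their local responses are interpolated by inverse distance weighting,
v(cell) = Σv_i d_i^−p / Σd_i^−p with p = 2 by default; a cell centred on a
sample takes that sample's value exactly, and all interpolated values are
convex combinations of the inputs. Surfaces cover the lek bounding box
with configurable padding and are written as ESRI ASCII grids (no-data
−9999).

Functional response lines are OLS fits of attendance change on density per
(radius, lag). The sustainable density for a declining line (slope < 0) is
the largest d with predicted change ≥ floor, clamped at 0; it is reported
in both pads/km² and literal pad count d·πr². A non-declining line has no
finite threshold and raises. Forecasts at current densities are combined
by the arithmetic mean of per-line predictions — no published aggregation
rule exists for this step, so the per-line vector is always emitted and
any alternative aggregation is recomputable. Opposing-response pairs
greedily match each increasing lek to the unused decreasing lek of nearest
density within a 5% relative tolerance; the matching rule is a
package choice, documented because no canonical rule exists.

## Synthetic study system

`simulate_study` defaults encode the emulated conditions: a 100 × 100 km
extent; pad activations Poisson with intensity 0.004 pads/km²/year growing
6.6 %/year over 1992–2011 (1.066²⁰ ≈ 3.6-fold, the observed two-decade
intensification; cumulative stock ≈ 1,500 pads by 2011, giving 2011 mean
lek-centred densities of ~0.1–0.2 pads/km², the observed order); lek
baseline attendance 25 males (≈ statewide mean attendance per lek);
sinusoidal periodicity of amplitude 5 males and period 6 years (the cycle
is documented but its magnitude is not, so amplitude and period are free
configuration with these defaults); counts over 2002–2011, Poisson by
default; and a step coefficient field of −4 (males/lek/year per pads/km²)
west of the midline, 0 east, on the 2-km density lagged 1 year.

Expected attendance is
m(i,t) = max(0, baseline + Σ_k β_k(x_i,y_i)·D_k(i, t−lag_k)·(t−t₀) +
A·sin(2πt/P)); truncation at zero (not a log link) keeps the linear trend
responses exactly recoverable in the noiseless limit. 'thomas' clustering
draws the year's Poisson total first and scatters it around uniform
parents (Gaussian spread 500 m, ~5 pads/parent), so the activation-count
law is identical across clustering modes while the geometry differs.

What the generator does **not** emulate: demographic mechanism (the lag is
phenomenological), detection probability ≠ 1, observer effort variation,
missing surveys (all simulated years are surveyed; the unsurveyed-year
path is tested separately), pad retirement, and real Wyoming geography.
Passing tests therefore demonstrate correctness of the machinery and
recoverability under the stated generative model — not that real lek data
meet that model.

## Scale of the shipped analyses

The default pipeline runs at 150 leks (the real database has ~814); the
GWR design uses three density columns ((1 km, 1 y), (2 km, 1 y),
(10 km, 3 y)) rather than all 20 radius × lag combinations, because
cumulative pad histories make same-radius different-lag columns nearly
collinear and the full design, while full-rank, is badly conditioned at
this n. Design keys are a parameter. Calibration of the permutation test
uses 500 null replicates × 99 permutations at n = 100 with one covariate;
n was fixed by a pilot power analysis (the variance statistic is
underpowered below n ≈ 80 on this design and saturates by n = 100), while
the type-I level is exact for any n. Step-field recovery is measured at
n = 400, noiseless, with leks within 10 km of the discontinuity excluded
from the error summary.

## Known limitations

- Gaussian-family inference treats the bandwidth as fixed when computing
  standard errors; selection uncertainty is ignored, as is standard.
- The F test's degrees of freedom are approximate (effective-parameter
  heuristics), so its size is near-nominal, not exact.
- The binomial family reports tr(S)-based complexity only.
- Local t-values use global residual degrees of freedom; whether to call
  them t or z at large df is cosmetic, and no per-lek multiplicity
  correction is applied by default.
- IDW surfaces have no search radius: every selected lek influences every
  cell, which is the conventional default but smooths long-range.
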