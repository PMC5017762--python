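# Methods

## Model

The engine computes the absolute 10-year risk of fatal CVD by a
competing-risks cumulative incidence with piecewise-constant
cause-specific hazards over 5-year age bands.

Let bands b = 1..B partition the horizon [a, a+10) of a person entering
at age a. Each band carries observed annual national mortality rates
m₁(b) (CVD) and m₂(b) (non-CVD), computed as deaths/population. The
person's hazards in band b are

    h₁(b) = m₁(b) · HR(b),   h₂(b) = m₂(b),
    HR(b) = exp( β_sbp (sbp − x̄_sbp(b)) + β_chol (chol − x̄_chol(b))
               + β_smoke (smoker − x̄_smoke(b)) ),

with x̄(b) the band's population means and x̄_smoke(b) the smoking
prevalence; the smoking indicator enters as (1/0 − prevalence), symmetric
with the continuous factors, so a person exactly at the band means has
HR = 1. The 10-year risk is

    risk = Σ_b S(b) · (h₁/h)(1 − e^{−h Δ_b}),   h = h₁ + h₂,
    S(b) = Π_{b'<b} e^{−h(b') Δ_{b'}},

with Δ_b the years of exposure in band b (Σ Δ_b = 10 exactly; two whole
bands for entry ages that are multiples of 5, three segments otherwise).
Computing the non-CVD incidence and survival with the same chaining
yields an exact partition of probability: CIF₁ + CIF₂ + S = 1 to
float precision, which the tests assert at 1e−12.

### Modelling assumptions

- **Markov/banded rates.** Hazards depend only on the current 5-year
  band; rates are constant within bands. This is the natural reading of
  band-aggregated national mortality tables and avoids interpolation
  that would contradict the banded population means.
- **Mean-person baseline.** The observed band rate is attributed to the
  person at the band means, so HR multiplies the observed rate directly.
  No E[HR] normalisation is attempted — it would require individual-level
  national data. This matches the established chart-recalibration
  practice of combining national baseline risk, external relative risks
  and national mean factor levels.
- **Band-wise reference.** HR is recomputed per band against that band's
  means: the person's measured values stay fixed over the horizon while
  the reference x̄ ages with them, because each band's observed rate
  reflects that band's mean levels.
- **Competing hazard unmodified.** Risk factors scale the CVD hazard
  only; non-CVD mortality enters at its observed rate.
- **Rates as hazards.** m = deaths/population is used directly as the
  annual hazard. In the intended regime (m < 0.05/y) the difference from
  the exact conversion −log(1−m) is far below chart rounding; a
  `strict_hazard_conversion` switch applies the exact form.

### The interpolated variant

The legacy method variant interpolates annual cause-specific rates
linearly in age between band midpoints (constant extrapolation beyond
the outermost midpoints) and chains 1-year steps, each step split at
band boundaries so its hazard ratio comes from its own band's means. For
chart-aligned integer entry ages the steps are exactly 1 year. Chosen
properties: when all bands share identical rates the variant reduces
*exactly* to the constant-rate method (asserted at 1e−9), and midpoint
anchoring keeps the interpolated curve through the observed band values.
How precisely the historical interpolation was defined is not
documented; this is the package's own reconstruction, used only for
sensitivity comparison.

## Charts

A chart grid is pure tabulation — each cell is bit-for-bit the direct
risk call for that (sex, smoking, age, SBP, cholesterol) profile. Default
axes: ages 40–65 by 5, SBP {120,140,160,180} mmHg, TC {4..8} mmol/L or
TC/HDL-C {3..7} (the ratio levels are this package's choice, configurable
via `ChartAxes`), both sexes, both smoking states: 480 cells, 320 when
restricted to ages 50–65. Display values round half-away-from-zero to
whole percent with "<1" below 0.5%; colour categories are
<1, 1, 2, 3–4, 5–9, 10–14, ≥15.

Chart comparison counts higher/lower/equal on rounded display values by
default (mirroring how chart readers experience the change; a raw-value
flag exists), reports mean and SD of |Δ| in percentage points on raw
values, and computes ICC(A,1) — two-way random effects, absolute
agreement, single measurement:

    ICC = (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE)),  k = 2.

Exact elementwise agreement is defined as ICC = 1 (including the
zero-variance case). The implementation is validated against a frozen
hand-computed 4-pair example (10/13) and cross-checked against an
independent library implementation in the test suite.

## Cohort application

Eligibility is a fixed cascade, each record counted at the first rule it
fails: (1) missing any risk variable, prior-CVD flag or positive weight;
(2) any prior CHD/stroke/heart-failure flag; (3) age outside [40, 65].
Risks use the exact recorded age via the three-segment horizon partition
(chart use, by contrast, rounds to the nearest chart age, ties up).

Weighted estimates use the Hájek ratio estimator Σwy/Σw with
Taylor-linearized SE, each record its own sampling unit and an n/(n−1)
factor; CIs are normal-approximation, truncated to [0,1]. Survey design
strata/cluster columns are accepted and ignored with a logged notice —
full design-based variance is out of scope. Estimates and SEs are
invariant to rescaling all weights (tested at 1e−12), and the SEs agree
with a 2000-replicate resampling bootstrap within 10% in the tests. The
high-risk threshold is inclusive: risk ≥ 5%.

## Synthetic data

The generator emulates the inputs a national recalibration consumes:

- **Mortality:** Gompertz cause-specific rates m(age) = m₀·e^{γ(age−40)}
  with sex multipliers, evaluated at band midpoints (midpoint evaluation,
  not the band-average integral, defines the band rate — consistent with
  the piecewise-constant model). Defaults (m₀ = 2e−4/y CVD, 1.2e−3/y
  non-CVD at 40; γ = 0.095 and 0.075 per year; female multipliers 0.55 /
  0.65; 100,000 person-years per cell) give band rates in the range of a
  contemporary low-to-moderate-CVD-mortality European country.
  Deterministic mode (expected counts) is the test default; Poisson mode
  adds sampling noise.
- **Survey:** ages uniform on [40, 75) so every band a 65-year-old's
  horizon needs is populated; SBP and TC normal with linear age trends
  (SBP 124/130 mmHg ± 17 at 40, +0.5/y; TC 5.5/5.6 ± 1.0 mmol/L,
  +0.02/y; HDL 1.6/1.3 ± 0.35, truncated > 0.3), smoking Bernoulli
  (26%/32%), log-normal weights (σ = 0.5), and optional planted
  missingness and prior-CVD flags whose ground-truth dispositions are
  returned for filter tests.
- **Coefficients:** illustrative defaults β_sbp = 0.015/mmHg,
  β_tc = 0.25/(mmol/L), β_ratio = 0.15/unit, β_smoke = 0.71 —
  epidemiologically plausible magnitudes for fatal-CVD hazards, marked
  `provenance="synthetic illustrative values"`. Real chart production
  must supply externally derived values.

What the generator does **not** emulate: two-stage cluster sampling and
nonresponse structure (weights are i.i.d.), secular trends, measurement
error, and correlation between risk factors and the planted prior-CVD
flags. Passing tests therefore demonstrate internal correctness of the
method under its own assumptions, not fidelity of any particular
published national chart.

The Monte-Carlo oracle draws per-band exponential times for both causes,
takes the earlier event within the band's exposure, advances survivors,
and returns the CVD-death fraction with binomial SE. The analytic engine
is required to agree within 4 SE at n = 200,000 across a 20-draw seeded
sweep — a few seconds of compute, giving Monte-Carlo noise well below a
chart cell's rounding resolution.

## Numerical choices

- `expm1` is used for 1 − e^{−x}; conservation holds to 1e−12.
- Floating comparisons default to absolute tolerance 1e−12 unless a
  looser tolerance is stated (1e−9 for cross-method equivalences, 1e−10
  for the end-to-end mean-profile identity).
- Chart-age rounding: nearest multiple of 5, ties (e.g. 42.5) round up,
  clamped to [40, 65].
- Zero total hazard in a band contributes zero incidence and unit
  survival; negative hazards and non-positive exposures are rejected.
- CSVs are written with `%.17g` and read with round-trip float parsing,
  so write→read is lossless.

## Known limitations

- National mortality tables include people with prevalent CVD, so the
  baseline overstates the risk of a CVD-free population; correcting this
  needs incidence data the method does not consume.
- Relative risks are applied to the CVD hazard only (cause-specific, not
  subdistribution); a Fine–Gray formulation is deliberately out of scope.
- Only fatal CVD and entry ages 40–65 are supported, the validity range
  of the underlying relative-risk estimates.
- Design-based survey variance (strata, clusters, calibration) is not
  implemented; the linearized SE assumes independent records.
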