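# Methods

## Setting and notation

The package operates on weekly mortality series in the STMF shape: for
each country/region, sex (`f`, `m`, `b`) and broad age group, a death
count and a weekly death rate (deaths per person-week) indexed by ISO year
and ISO week. Write *x<sub>ij</sub>* for the selected measure in week *i*
of year *j*, *T* for the target year, *P* for the reference period (a set
of years that may include *T*), and *W* for the weeks available in the
target year (|W| < 52 for incomplete years). Week labels are taken as
given; no date arithmetic is performed beyond checking that week 53 only
occurs in 53-week ISO years (a year has 53 ISO weeks iff 28 December
falls in week 53).

## The six reference levels

Two families express two different notions of "expected" mortality.

**Week-varying** — the reference varies by week and encodes the recent
history of the same week:

1. *Week-specific average*: x̄ᵢ = Σ_{j∈P} xᵢⱼ / |P|. The workhorse of
   surveillance practice (national statistics offices, newspapers).
2. *Week-specific trend*: x̂ᵢ = âᵢ + b̂ᵢT, with (âᵢ, b̂ᵢ) fitted by
   ordinary least squares on {(j, xᵢⱼ) : j ∈ P}, one independent
   regression per week. Appropriate where mortality has been steadily
   falling (or rising) over the reference years, which biases the plain
   average.
3. *Week-specific lower quartile*: the mean of the week's values at or
   below the week's lower quartile. A "good conditions" baseline per
   week.

**Week-constant** — the reference is one number per target year and
encodes within-year seasonality:

4. *Yearly average-week*: x̄ = Σ_{i∈W} x̄ᵢ / |W|.
5. *Summer average-week*: the same mean restricted to non-winter weeks
   W\* (winter: weeks 1–12 ∪ 48–52 in the north, 22–38 in the south).
   Designed for heat-wave and other out-of-winter elevations; since
   winter weeks are usually the high-mortality weeks, x̄\* ≤ x̄ is the
   typical (not guaranteed) ordering. The sufficient condition — every
   winter-week x̄ᵢ at least every non-winter x̄ᵢ — is asserted as a
   property test. The constant is replicated over all requested weeks,
   including winter ones, so the full target year can be differenced
   against it.
6. *Yearly lower-quartile-week*: pool **all** values xᵢⱼ with j ∈ P over
   all weeks, take one lower quartile, and average the values not above
   it. A data-driven "low-mortality season" constant.

A deliberate reading choice, applied consistently: quartile membership
uses ≤ (values tied with the quartile are included), and the yearly
lower-quartile pool ranges over all weeks of all reference years. With
|P| = 1 the week-specific average is the identity on the reference year,
and the constant methods express purely within-year comparisons.

No confidence intervals are attached to any baseline. The point of this
method family is transparency and comparability, not inference; users
needing uncertainty should fit an explicit count model.

## Quartiles

All quartiles are type-7: with sorted values x₍₁₎…x₍ₙ₎ and
h = 1 + (n−1)p, the p-quantile is x₍⌊h⌋₎ + (h−⌊h⌋)(x₍⌈h⌉₎ − x₍⌊h⌋₎).
This is the default of both R's `quantile` and numpy's `"linear"` method,
so results are directly comparable with the common statistical
environments. The test suite checks the implementation against an
independent closed-form evaluation.

## Excess, polygons, summaries

Per week, excess = observed − reference, computed by exact floating-point
subtraction (no smoothing). An *excess polygon* is a maximal run of
consecutive available weeks with strictly positive difference (deficit:
strictly negative). Three conventions are fixed and tested:

- zero-difference weeks belong to no polygon (strict sign);
- a gap in the available weeks terminates a run;
- polygon boundaries are whole weeks — no sub-week crossing
  interpolation, so length = end − start + 1.

Selections [week_from, week_to] are summarised as **sums** for death
counts and **unweighted means** for death rates. Rates are not
person-week-weighted because exposures are not part of the data model;
the unweighted mean matches how weekly rates are usually averaged in this
setting. Requested weeks without data are excluded and reported, so a
selection is week-dependent by construction.

Nearest-point lookup (for outlier identification in overlay plots)
minimises Euclidean distance after per-axis normalisation, with ties
broken toward the earlier year, then the earlier week.

## Missing data and week 53

Real STMF series are ragged at the start and end. The estimators never
impute: per-week statistics are computed over the reference years that
actually observe the week (the denominator is the count of available
years, logged when short of |P|), the trend requires at least two
observations per week, and weeks with no reference observations are
errors, not zeros. Week 53 gets one special rule: if no reference year
contains week 53, the week-52 reference value is carried forward and
flagged in `diagnostics["week53_fallback"]`. Without this rule every
53-week target year (2020 being the prominent one) would silently lose
its final week — often the epidemically interesting one.

## Numerical choices

- **Per-week OLS** is computed in centered form: b̂ = Σ(j−ȷ̄)(x−x̄) /
  Σ(j−ȷ̄)², prediction x̄ + b̂(T−ȷ̄). Centering keeps the computation
  well-conditioned at calendar-year magnitudes; exactly linear input is
  reproduced to machine precision (tested at 1e-9 relative). Coefficients
  are reported in the calendar-year parameterisation (âᵢ = x̄ − b̂ȷ̄).
- **Means of identical values short-circuit** to the common value, so a
  series constant in week and year passes through every baseline
  unchanged and produces exactly zero differences — the degenerate
  agreement property would otherwise be violated by one-ulp pairwise
  summation artifacts.
- **Pooled values are sorted before averaging** in the yearly
  lower-quartile method, making all estimators invariant to the input
  ordering of records.
- **CSV round-trips are byte-exact**: floats are written in shortest
  round-trip representation and parsed with round-trip precision, so
  write∘read∘write is byte-identical and CLI outputs match library
  outputs bit for bit.

## The synthetic generator

The generator emulates what the estimators assume about real weekly
mortality, with expected both-sex deaths

    μ_ij = (α + β·(j − j₀)) · (1 + γ·cos(2π(i − φ)/52)),

defaults α = 1000 deaths/week, β = 0 (set negative to mimic the secular
mortality decline seen in many countries), γ = 0.15, φ = week 2 — a
winter-peaking cosine, so Northern-winter weeks are elevated and the
summer average-week ordering is exercised. Week 53, generated only for
53-week ISO years, reuses the week-52 seasonal factor, which exercises
the week-53 fallback. An optional shock adds K extra expected deaths over
a window of one year, spread flat or triangularly; `ground_truth_excess`
returns the exact allocation to any query window. Under `noise="none"`
counts equal expectations (fractional counts are valid table values);
under `"poisson"` each age-group count is an independent Poisson draw so
the total is Poisson with the intended mean. Age groups split the total
as (0.005, 0.105, 0.15, 0.27, 0.47) — an elderly-heavy pattern that is
plausible but arbitrary; no ground truth depends on it. Female and male
series each carry half the both-sex expectation (with independent noise).

What the generator does **not** emulate: overdispersion beyond Poisson,
reporting delays and revisions, holiday artifacts, age-structure change
over time, and correlated multi-year epidemics. Passing recovery tests
therefore demonstrates correctness of the estimators under their own
assumptions, not robustness to those real-data features.

Study conditions used by the recovery tests and the acceptance script:
years 2015–2020, target 2020, reference 2015–2019, flat shock K = 1300
over weeks 10–22 (13 weeks), 100–200 Poisson replicates. With stationary
noise-free reference years the week-specific average recovers K exactly;
with β = −20/year it understates K (the older, higher reference years
pull the baseline up) while the trend baseline still recovers K to 1e-9
relative; under Poisson noise the replicate mean lies within 3 standard
errors of K.

## Plotting

Figures are static matplotlib renderings of the standard panel: target
year curve, dashed reference level, shaded excess/deficit polygons
(SVG group ids `stmfx-polygon-<k>`, so shading is machine-checkable),
optional light-gray overlay of all other years. The legend always names
the target year, method and reference period, so images are
self-describing. SVG output is byte-deterministic (fixed hash salt, no
date metadata, text kept as text); palettes change colors only, never
geometry.

## Interface conventions

The CLI exposes the selection surface as flags (`--country`, `--sex`,
`--measure`, `--target-year`, `--reference-years`, `--method`,
`--hemisphere`, `--weeks`) and maps failures to exit codes: 2 for
validation/schema/selection problems, 3 for estimator preconditions
(e.g. the trend method with a single reference year). When
`--reference-years` is omitted, the period defaults to up to 7 available
years preceding the target year, mirroring common surveillance practice
of 4–7 preceding years. Hemisphere defaults to a bundled lookup of
Southern-Hemisphere STMF codes (everything else north) and can be
overridden explicitly.

## Known limitations

- Only CSV input is supported (not xlsx), and only the canonical header
  dialect; extra columns are ignored, never interpreted.
- The six baselines are deliberately simple; Serfling-type regression,
  Poisson/negative-binomial GLMs and spline baselines are out of scope.
- Rates are averaged unweighted; population-weighted aggregation would
  require exposures the table does not carry.
- The bundled hemisphere table covers the Southern-Hemisphere STMF codes
  only; unknown codes default to north.
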