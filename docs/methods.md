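# Methods

This note documents the models and procedures implemented in `tenamericas`,
the defaults they use, and what the synthetic-data experiments do and do not
demonstrate.

## Partition of county × race/ethnicity units

Every combination of county and race/ethnicity (AIAN, Asian incl. NHPI,
Black, Latino, White; all but Latino refer to the non-Latino population) is
assigned to exactly one of ten groups by fixed rules (`classify`):

* **Latino** → America 5 in the Southwest (AZ, CO, NM, TX), else America 2.
* **Asian** → America 1 where the NHPI share of the Asian+NHPI population is
  below 0.30, else America 3.
* **AIAN** → America 10 in the 14 Western states (AZ, CO, ID, KS, MN, MT,
  NE, NV, NM, ND, OK, SD, UT, WY), else America 3.
* **Black** → America 7 in RUCC-1 counties with Black–White dissimilarity
  ≥ 60; America 9 in non-metropolitan (RUCC 4–9), low-income counties of the
  Lower Mississippi Valley or Deep South; else America 6.
* **White** → America 4 in non-metropolitan, low-income Northlands counties
  (IA, MN, MT, NE, ND, SD); America 8 in low-income Appalachia/LMV counties;
  else America 3.

"Low-income" is a race-specific county income per capita strictly below
$32,363 (the 2020 all-race county median). The America-7 rule is evaluated
before the America-9 rule; under valid attributes the two cannot co-occur
(RUCC 1 vs 4–9), so the precedence exists purely for deterministic behaviour
on malformed inputs. Raising a county's White income across the threshold
can only move its White unit into the residual America 3, never the other
way — this monotonicity is property-tested.

The dissimilarity index is D = 50·Σᵢ|bᵢ/B − wᵢ/W| over subunits (tracts),
0 for identical distributions, 100 for complete segregation; it is undefined
(an error) when either group's total is zero.

## Misclassification correction

Race/ethnicity recorded on death certificates sometimes differs from
self-identification, biasing race-specific rates because numerator and
denominator then disagree. The correction is population-level: recorded
counts are multiplied by misclassification ratios (self-reported /
recorded). Implementation choices:

* **Ratio uncertainty.** Each ratio with standard error SE receives
  `n_sims` (default 1000) log-normal draws, moment-matched on the
  *arithmetic* scale: σ² = ln(1 + SE²/mean²), μ = ln(mean) − σ²/2, so the
  draws' mean equals the ratio and their SD the SE. SE = 0 yields a
  degenerate draw set.
* **Combination across dimensions.** Ratios are published along several
  stratifications (broad age band × sex; census region; co-ethnic density
  tercile for AIAN and Latino). Per simulation s the combined ratio is
  overall(s) · Π_d [component_d(s) / overall(s)] — a multiplicative
  main-effects rule that returns the overall ratio when no dimension
  deviates and the single active component when only one does. The rule is
  isolated in one function so an alternative interaction treatment can be
  substituted without touching callers. A dimension level missing from the
  table (e.g. excluded for zero deaths) contributes no deviation, with a
  warning.
* **Rescaling.** After multiplication, counts are rescaled within each
  (year, county, age, sex, simulation) by raw-total/corrected-total, so the
  correction reallocates deaths between race labels but never changes how
  many deaths occurred. Single-race strata are therefore exact fixed points.
* **Stochastic variation.** After pooling deaths to America × year × age ×
  sex × simulation, each cell is replaced by one Poisson draw with the cell
  value as its rate. Pooling precedes the Poisson layer; each simulation
  uses an independent stream spawned from the root seed, so results are
  reproducible under any execution order.
* **Standard errors in the synthetic tables** use the delta method for a
  ratio of Poisson totals, SE ≈ ratio·√(1/num + 1/den). Real applications
  would take SEs from the linkage study that produced the ratios; the delta
  method is this package's documented stand-in and is flagged in the
  configuration (`ratio_se_method`).
* **Multiple-race bridging.** Deaths recorded in a "Two or More Races"
  category (present in years after race bridging was discontinued) are
  reallocated to single races proportionally to the local single-race
  composition of the stratum. Proportional allocation is a documented
  stand-in for the original bridging algorithm; totals are conserved
  exactly.

## Population harmonisation

* **Two-or-more-races split.** Reported multirace population is allocated
  to single races proportionally to the local single-race composition,
  conserving cell totals exactly.
* **Intercensal blend.** Postcensal estimates carried forward from an old
  census base disagree with the next base ("error of closure"). The blend
  computes the base-date discrepancy per (county, age, sex, race) cell —
  new-base value minus the old series log-linearly extrapolated from its
  last two years — and adds w(t)·discrepancy with w linear from 0 at the
  window start (default: ten years before the base) to 1 at the base date.
  The blended series meets the new base exactly at the base date. A
  multiplicative variant (`linear_multiplicative`) raises the per-cell
  closure factor to the power w(t); the strategy is pluggable so the exact
  official procedure can replace the default. Cells a negative discrepancy
  would drive below zero are floored at 0 and counted.

## Life tables

Abridged schema: 0, 1–4, then 5-year groups to 80–84, plus open 85+ (19
groups). Conversions follow the standard abridged conventions:

* a(0) = 0.07 + 1.7·m(0) (infant deaths concentrated early in the year);
  a = n/2 for other closed groups. The convention is confined to one
  function and can be replaced.
* q = n·m/(1 + (n − a)·m), capped at 1; q = 1 in the terminal group.
* Radix 100,000; L = n·l(x+n) + a·d(x); terminal L = l(85)·e(85);
  T is the reverse cumulative sum of L; e = T/l.
* **Terminal e(85).** Default strategy `constant_hazard`: e(85) = 1/m(85),
  exact for a stationary population with a flat hazard. The alternative
  `horiuchi_coale` applies a first-order stable-population correction
  e(85) = (1/m)·exp(−β·r) with r the population growth rate at the terminal
  ages: in a growing old-age population the observed death rate
  under-weights the oldest (highest-mortality) ages, so 1/m overstates
  remaining life expectancy. β (default 5.5 years) plays the role of the
  age-exposure covariance in the open interval; the published
  growth-adjusted estimator can be slotted into the same strategy hook. The
  two strategies coincide at r = 0 and both are strictly decreasing in m.
* **Partial (temporary) life expectancy** over [x1, x2) is
  (T(x1) − T(x2))/l(x1): mean years lived in the range per person alive at
  x1, bounded by the range width. Note the telescoping identity takes the
  survival-weighted form e0 = Σ (l(x1)/l(0))·pLE(x1,x2) + (l(85)/l(0))·e(85)
  — each partial is per survivor to its own range start, so the unweighted
  partials do not sum to e0.
* **Ensemble summaries.** Point estimate = mean of simulation draws; 95% UI
  = 2.5th–97.5th percentiles with linear interpolation between closest
  order statistics (stated explicitly because 1000 draws leave visible
  interpolation choices).

Pooled rates are computed after aggregating deaths and population to
America level — the stratum rate is Σdeaths/Σpopulation, never an average
of county rates. Zero population with nonzero deaths is an error; zero/zero
yields rate 0 with a warning.

## Synthetic-data generator

The generator (`synthetic`) emulates the statistical structure the analysis
assumes; its defaults are the study conditions the test suite exercises.

* **Counties** (default 200): state uniform over the 50 states; RUCC drawn
  with metro codes rarer than rural ones; base population log-normal
  (median 25k, σ = 1.1) with metro multipliers; race composition Dirichlet
  around national-share means (AIAN 3%, Asian 7%, Black 14%, Latino 16%,
  White 60%); race-specific income below the $32,363 threshold with
  probability `low_income_fraction` (0.5); Black–White dissimilarity
  computed from synthetic tract counts whose concentration parameter spans
  integrated to highly segregated counties; NHPI share Beta(1.5, 10);
  regional flags (Appalachia, LMV, Deep South) sampled with per-state
  probabilities, since the real membership lists are external resources.
  The generator rejects configurations whose county draw leaves any America
  empty, naming the empty Americas.
* **Population**: smooth per-cell series, fixed age pyramid and sex split
  (50.8% female), per-(county, race) growth ~ N(0.4%, 0.4%). Reported
  series adds (a) an old-base measurement error growing linearly over the
  decade before `discontinuity_year` (2020) and reaching ±`discontinuity_scale`
  (3%) just before it — an abrupt census-base jump — and (b) a reported
  "Two or More Races" category from the base year onward (per-race
  fractions: AIAN 15%, Asian 5%, Black 3%, White 2%).
* **Deaths**: Poisson with expectation population × h(age midpoint), where
  h is a race-specific Gompertz–Makeham hazard h(x) = c + a·e^{bx} and
  males carry a 1.55× proportional excess. Levels were calibrated once so
  both-sex life expectancy at birth spans a realistic range (AIAN ≈ 71,
  Black ≈ 72.5, White ≈ 77.5, Latino ≈ 80.5, Asian ≈ 83 years).
* **Misreporting**: each true-race death's recorded race is one categorical
  draw from a row-stochastic matrix; stratum totals are conserved exactly
  (integer multinomial flows). The default matrix records a quarter of AIAN
  deaths as White, ~5% of Asian and ~4.5% of Latino deaths as other races,
  and is near-diagonal for Black and White. The matrix is constant over
  age, sex and region; the dependence of net ratios on co-ethnic density
  then emerges mechanically (in AIAN-dense counties the White→AIAN inflow
  is relatively smaller), which is exactly why the density dimension is a
  useful ratio stratifier.

What the generator does *not* emulate: cause-of-death structure, migration
and cohort dynamics, county boundary changes over time, age- or
region-varying misreporting, NHPI-specific mortality, and real geographic
income/segregation correlations. Passing tests therefore demonstrate the
pipeline's internal correctness and its behaviour under a plausibly
structured data-generating process — not agreement with the published
national estimates, which require restricted microdata and enter the
package only as a transcribed fixture for the reporting arithmetic.

## Recovery experiments and problem sizes

The end-to-end check (`validation.run_recovery`) runs 200 replicates at 200
counties, 5 races, one year, 100 simulations. Each replicate draws a fresh
county set and two independent death realisations: a "linkage study"
realisation that yields the misclassification-ratio tables (so ratio error
is genuinely external to the analysed data, as in reality), and an analysis
realisation that is corrected and fitted. Truth is computed exactly from
the known hazards (pooled expected rates → life table). Measured outcomes:
the corrected America-level e0 is markedly less biased than the uncorrected
one for the heavily misreported AIAN group, and pooled 95%-UI coverage of
truth across Americas × replicates sits near the nominal level (the test
accepts 90–98%). These sizes keep the full suite within a few minutes on
one CPU while leaving per-America death counts large enough for the
asymptotics the correction relies on.

## Numerical and degenerate-input choices

* Strata with zero recorded or zero self-reported deaths are excluded from
  ratio tables (warned and logged); mean ≤ 0 ratios are rejected.
* `apply_and_rescale` errors if a stratum's corrected total is zero while
  its raw total is positive (impossible with strictly positive ratios).
* A terminal death rate of zero (no one survives to 85, or no deaths) gives
  zero terminal person-years rather than an infinite expectancy.
* Display rounding is one decimal, half away from zero; all internal
  computation is unrounded. Gap/ranking ties are broken by reporting all
  tied Americas, lowest id first, and tied ranks share the lower rank
  number and are flagged.
* The published-estimates fixture contains one rounding inconsistency
  inherited from its source: the 2010 gap prints as 13.9 while the rounded
  levels give 14.0; consumers comparing against the fixture should allow
  ±0.1 years for that cell.

## Known limitations

* The multiplicative main-effects combination rule ignores interaction
  between ratio dimensions; if the true misclassification surface has
  age×region interactions the combined ratios are approximations.
* The delta-method SEs understate uncertainty if the linkage sample is
  clustered; coverage statements are conditional on the generator's
  independence assumptions.
* The growth-adjusted terminal strategy is first-order; at extreme old-age
  growth rates (|r| > ~3%/yr) its exponential form is an extrapolation.
* Intercensal blending distributes closure error linearly; the official
  procedure differs in detail (hence the pluggable strategy).
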