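# Methods

This note records the model's assumptions, parameter conventions, numerical
choices, and the design decisions taken where the design was genuinely
open. It states no empirical result that the tests or
`scripts/acceptance.py` do not themselves compute.

## Model structure

The simulator is an open-population, discrete-time microsimulation with an
annual cycle. A cycle labelled `Y` covers `[Y, Y+1)`. The supported
calendar range is 2001–2065; population *estimates* exist through 2019 and
*projections* (by scenario label) thereafter, so a base year after 2019
triggers a silent fast-forward: the engine simulates from 2019 and records
from the base year.

Within a cycle the event order is fixed:

1. age increment → 2. births → 3. net immigration (entrants receive risk
factors and prevalence-equation labels) → 4. incidence (unlabelled
residents) / reassessment (labelled residents) → 5. control intercepts for
new labels → 6. control proportions → exacerbations → severity →
7. payoffs → 8. deaths → 9. emigration.

Payoffs therefore accrue in full for individuals who die or emigrate in the
same cycle. Entrants are excluded from same-cycle incidence and
reassessment: their label already reflects the prevalence equation at the
entry year, and reassessing them in the entry cycle would double-apply
remission. Per-sex demographic conservation —
`pop(Y+1) = pop(Y) + births(Y+1) + immigrants(Y+1) − deaths(Y) − emigrants(Y)` —
holds exactly and is asserted in tests.

### Conventions

- Sex is binary, encoded female = 0, male = 1 in every table.
- Ages are completed years, 0-based. The oldest tabulated age is absorbing
  for lookups (older ages clamp to the last row); the open-ended oldest
  age group of source tables is handled by pooling its survivors in the
  migration accounting and by setting the fixture life table's last-age
  death probability to 1.
- Scaled counts are rounded half-up deterministically (not stochastically)
  so small-scale runs are exactly reproducible.

## Structural equations and parameters

**Family history (FHA).** A single Bernoulli probability (default 0.293)
applied to every entrant regardless of year and sex; survey trend data
support treating it as stable.

**Infant antibiotics (IAE).** Courses in the first year of life are
negative binomial with variance `μ + μ²/θ`. The log-mean is linear in sex
and calendar year with an intercept/slope change after the knot year
(2005). The year covariate is centred at 2000 — the source coding is
unstated, and raw calendar years would make printed-magnitude coefficients
unusable — and the knot year is configurable. The mean is floored at 0.05
(50 courses per 1,000 infants) to prevent unrealistic downward
extrapolation. Entrants at age ≥ 1 draw their IAE from their *birth* year's
mean, since the occurrence equations need IAE at ages 3–7 and immigrants
are assumed to share national exposure rates.

**Occurrence.** Prevalence and incidence are logistic regressions. The
polynomial coding is raw centred powers — year enters as `(year−2010)/10`,
age as `(age−40)/40` — with per-sex coefficient blocks: 34 prevalence
coefficients (per sex: year, year², age…age⁵, and the 10 year×age
interactions) and 10 incidence coefficients (per sex: age…age⁵) plus a
shared year slope. Orthogonal-polynomial coding was deliberately not
assumed; the coding is recorded here and in the schema so fixture
coefficients are self-consistent. Calendar year is clamped into
[2000, stabilisation year] (default 2025) before expansion, making rates
flat outside that window. No label is assigned below `min_asthma_age`
(default 3). Risk-factor log-odds-ratio add-ons: FHA contributes
`b0 + b1·(min(age,5)−3)` from age 3; IAE contributes
`b0 + b1·(age−3) + b2·min(dose,3)` inside ages 3–7 for any positive dose.
Remitted individuals who later re-incide get the same age/dose-determined
effects (the effects carry no memory of the label history).

**Control.** Proportional-odds ordinal model over uncontrolled / partially
controlled / well-controlled, with per-sex age and age² fixed effects (age
coded `(age−40)/40`) and a person-level `N(0, σ²)` intercept drawn once at
first labelling and kept for life — including across remission and
relabelling — as a latent severity trait. The three cumulative-logit
fractions are used directly as expected control-time shares; they sum to 1
by construction.

**Exacerbations.** Poisson with log-mean
`offset + Σⱼ CTⱼ·log(rateⱼ)` and default per-level rates 0.564 / 0.376 /
0.188 events per person-year. Because the log-mean is a convex combination
of the per-level log-rates, the zero-offset mean always lies in
[0.188, 0.564] (property-tested).

**Severity.** A probability 4-vector per person-year from
`Dirichlet(α)`, default `α = (3.2, 2.0, 0.6, 0.2)` (synthetic; the source
concentration values are not public). Very-severe history inflates the
fourth component by `(1+γ)^min(history, cap)` with renormalisation
(defaults γ = 0.25, cap = 3). This functional form is this package's own
construction — the original's is in unavailable supplementary material —
and is configurable and clearly non-canonical. History never decreases.
For prevalent cases at model entry, onset age is uniform between the
minimum asthma age and current age, and past very-severe count is Poisson
with mean = years-since-onset × the zero-intercept baseline very-severe
rate; this initialisation is likewise a documented stand-in.

**Payoffs.** Baseline utility: 1 at birth, linear to the sex-specific
age-18 value (0.881 female / 0.875 male), then a tabulated adult curve
(synthetic default: gentle linear decline, clamped at the oldest entry).
Control disutilities per full year: 0.10 / 0.09 / 0.06 (UC/PC/WC).
Exacerbation disutilities per event: full-year values 0.32 / 0.44 / 0.50 /
0.56 (severe = midpoint of moderate and very severe, enforced by a
validator) pro-rated by duration (1 week mild, 2 weeks otherwise; a single
mild event is `0.32/52 ≈ 0.006`). Person-year utility is floored at 0 —
negative QALY weights from extreme event loads would be nonsensical. Costs:
annual control tariffs and per-event severity tariffs in 2023 CAD; the
level values are synthetic (the sourced tariffs are not printed publicly)
but respect the stated structural rule severe = geometric mean of moderate
and very severe. No discounting and no half-cycle correction in v1; a
discount hook would apply only at aggregation.

## Calibration (reconstructed procedures)

The original calibrations live in unavailable supplementary material; each
solve here is a documented reconstruction from the main-text descriptions,
and each result is labelled "reconstructed procedure".

**Net migration.** Deterministic survivor accounting between consecutive
population-table years: expected counts are last year's thinned by the life
table (with top-age pooling) or the birth cohort at age 0; positive
shortfalls become immigrant counts at the destination cell, surpluses
become emigration probabilities on the source cohort. Probabilities above 1
are infeasible and raise with the offending stratum named.

**Occurrence offsets.** The crude target for each (year, sex, age) cell is
the base (risk-factor-free) occurrence equation itself; the additive logit
offset `δ` solves
`Σ_cells w(cell)·invlogit(η + effect(cell) + δ) = target` by bracketed
Brent root-finding to 1e-10, where the cells enumerate the joint
(FHA, capped IAE dose) distribution of the cohort (FHA Bernoulli ×
negative-binomial dose categories 0,1,2,3+ from the birth-year antibiotic
mean). For *incidence*, the weights are conditioned on being unlabelled —
`w·(1 − P(labelled | cell))` per the offset-corrected prevalence equation —
because incidence acts on a pool depleted of high-risk cells; solving
against the whole-cohort distribution leaves a measurable downward
prevalence bias.

**Reassessment.** Cohort accounting between consecutive targets:
`p1 = p0·keep + (1−p0)·inc` along (Y, a) → (Y+1, a+1), with mortality
assumed label-independent (it cancels from the fraction). Solved
keep-probabilities are stored at the destination cell, where the engine
looks them up. Where `keep` leaves [0, 1] it is clamped and the cell's
incidence target absorbs the remainder (`(p1−p0)/(1−p0)` at keep = 1,
`p1/(1−p0)` at keep = 0); this joint treatment is consistent with
incidence itself being partly calibration-sourced, and without it new
age-3 cohorts — which can only be seeded through incidence — drift below
the prevalence targets. The ordering (offsets and reassessment solved from
the same crude targets, migration independently) is this package's choice;
the original's ordering is unstated.

**Exacerbation offset.** `offset = log(target very-severe rate) −
log(simulated zero-offset rate)`, with the baseline estimated from `n_sim`
simulated person-years (default 200,000) and a Monte-Carlo standard error
of `1/√(total very-severe events)` on the log scale. `calibrate_all` leaves
this offset at 0 because no external very-severe rate table ships with the
package.

## Randomness and determinism

Four independent substreams (demography, risk factors, occurrence,
outcomes) are spawned from the run seed, so changing one module's
parameters does not perturb another module's draws (tested). Runs are
byte-identical for a fixed seed. Because streams are per-module rather
than per-individual, results are *not* invariant to `population_scale`
changes — a different scale reshuffles everyone's draws.

## Synthetic fixtures: what they emulate and what they do not

`generate_fixture_inputs` produces tables with the shape of national
statistical-agency exports: a smooth pyramid totalling ≈38 million in 2019
growing 1%/year, Gompertz-like death probabilities that are monotone in
age, improve slowly over calendar time, and reach 1 at the oldest age, and
births equal to the age-0 counts. A small seeded jitter (±0.5%) makes
distinct seeds produce distinct but equally plausible tables. They are
*not* real census data: no cohort effects, no migration waves, no
period mortality shocks. Default regression coefficients are likewise
synthetic, chosen once for epidemiological plausibility (childhood-peaked
prevalence around 8–12%, childhood-peaked incidence of a few per 1,000,
declining infant antibiotic prescribing reaching the floor in the 2030s);
scalar values printed in the literature (0.293; 0.564/0.376/0.188;
utilities, disutilities, durations; the 0.05 floor) are used directly.
Passing tests therefore demonstrate the *mechanics* — conservation,
calibration self-consistency, tariff arithmetic, distributional
correctness — not agreement with any real population's burden estimates.

## Numerical choices

- Root solves: Brent's method on [−50, 50] logits, tolerance 1e-10; the
  marginal is strictly monotone in the offset so the root is unique.
- Deterministic half-up rounding for scaled counts.
- Life-table, offset and keep-probability lookups clamp year and age to
  the tabulated range.
- Degenerate inputs: zero births give empty cohorts; empty migration
  tables mean no flows; `σ = 0` gives identically-zero intercepts;
  multinomial splitting skips zero counts.
- Test problem sizes: engine runs use fixture populations at scales
  2×10⁻⁴–5×10⁻⁴ of the full pyramid over 6–7 years (≈7,600–19,000
  individuals), moment checks use 10⁵–10⁶ draws; both chosen as the
  smallest sizes at which the 3-standard-error criteria are informative.
- The prevalence-tracking check compares labelled counts to
  target-implied expectations per year; per-year z-scores are positively
  autocorrelated (labels persist across years), so the criterion bounds
  the mean z (conservative, since the mean of unit-variance positively
  correlated z's has standard deviation at most 1) with a per-year guard.

## Known limitations

- Diagnosed ("labelled") asthma only; no true-disease or diagnosis-error
  module.
- Net migration flows only; no gross flows, households, or geography.
- No treatment/medication modelling, no indirect costs, no caregiver
  utility, no parameter uncertainty (single deterministic parameter set).
- The severity history-inflation form and the prevalent-case
  initialisation are stand-ins, flagged above.
- The mortality adjustment is a plain multiplier on life-table
  probabilities; the source's adjustment form is unavailable.
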