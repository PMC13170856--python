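# asthmasim

An open-population, annual-cycle microsimulation of diagnosed asthma in a
national population, for health-economic and policy analysis. Each virtual
individual carries a sex, birth year, two early-life risk factors (family
history of asthma, infant antibiotic courses), a diagnosed-asthma label, a
latent control trait, an exacerbation history, and accumulating QALY/cost
payoffs. The population is open: people enter through birth and net
immigration and leave through death and net emigration, so the simulated
pyramid tracks a national population (≈38 million in 2019 at full scale)
from 2001 to 2065.

The package is aimed at modellers who need a transparent, fully synthetic-
data-capable asthma policy model: every input table can be generated by the
built-in fixture generator, or replaced by real statistical-agency exports
with the same schema.

## Model core

Per cycle (year `Y`, covering `[Y, Y+1)`), for individual `i`:

- **Demographics.** `(sex_i, age_i) ~ Categorical(p(sex, age) | year)` for
  the base-year population; `sex_i ~ Bernoulli(p_male | year)` for births;
  `death_i ~ Bernoulli(q(year, sex, age))` from the life table; net
  immigrant counts and emigration probabilities come from calibration.
- **Risk factors.** `FHA_i ~ Bernoulli(p)` with `p = 0.293`;
  `IAE_i ~ NegBin(max(0.05, μ), θ)` with
  `log μ = β₀ + β₁·sex + β₂·1[year>2005] + β₃·(year−2000) + β₄·1[year>2005]·(year−2000)`.
  The 0.05 floor keeps simulated infant prescribing at ≥50 courses per
  1,000 infants however far the declining trend is extrapolated.
- **Occurrence.** Prevalence (entrants) and incidence (residents) are
  logistic: `logit p = β₀ + β⃗·[poly(year,2) × sex × poly(age,5)] + FHA(age) + IAE(dose, age) + δ`,
  with the year clamped into [2000, 2025] (the stabilisation year), no
  label below age 3, and `δ` a calibrated per-cell offset. Labelled
  individuals are reassessed annually and keep the label with a calibrated
  probability; losing it returns them to the susceptible pool.
- **Outcomes.** Control is proportional-odds ordinal
  (`logit P(Y ≤ j) = θⱼ − (β₀ᵢ + β⃗·sex × poly(age,2))`, `β₀ᵢ ~ N(0, σ²)`
  drawn once per person) giving the fractions of the year uncontrolled /
  partially / well controlled. Exacerbations are Poisson with
  `log μ = δ + Σⱼ CTⱼ·log rateⱼ`, anchored at annual rates 0.564 / 0.376 /
  0.188 for pure uncontrolled / partial / well-controlled years. Each
  event's severity (mild/moderate/severe/very severe) follows a
  Dirichlet-multinomial with very-severe-history inflation.
- **Payoffs.** Baseline utility is 1 at birth, linear to the age-18 value
  (0.881 female, 0.875 male), then tabulated. Control levels cost
  0.10/0.09/0.06 QALY per full year (UC/PC/WC); exacerbations cost their
  full-year disutility (0.32/0.44/0.50/0.56) pro-rated by duration (1 week
  mild, 2 weeks otherwise). Direct costs are control-time-weighted annual
  tariffs plus per-event severity tariffs, with the severe cost the
  geometric mean of the moderate and very severe costs.
- **Calibration.** Deterministic solves for net migration (survivor
  accounting), label-retention probabilities (cohort accounting), and
  occurrence offsets (bracketed root-finding so risk-factor-marginal rates
  hit the crude targets), plus a simulation-based exacerbation intercept.

## Worked example

```bash
asthmasim fixtures  --out fx --year-start 2018 --year-end 2026
asthmasim calibrate --inputs fx --params fx/parameters.json \
                    --base-year 2019 --horizon 2025 --out cal
asthmasim simulate  --inputs fx --params fx/parameters.json --calibration cal \
                    --seed 1 --scale 0.0002 --base-year 2019 --horizon 2025 --out run
```

The simulate step logs, per cycle, the scaled population, labelled count
and total exacerbations:

```
INFO year 2019: pop 7599, labelled 848, exacerbations 267
INFO year 2020: pop 7682, labelled 860, exacerbations 237
...
INFO year 2025: pop 8057, labelled 930, exacerbations 284
```

At `--scale 0.0002`, 7,599 individuals stand in for ≈38 million; the
labelled count corresponds to a prevalence of ≈112 per 1,000 in 2019,
rising slightly to the stabilisation year as the calibrated occurrence
trend plays out. `run/summary.csv` holds per-year × sex aggregates; the
first data row

```
2019,0,4328,467,107.9,955.5,200.6,0.8608
```

reads: females in 2019 — 4,328 simulated, 467 labelled (107.9 per 1,000),
annual per-patient control cost ≈$955, per-patient exacerbation cost
≈$201, mean utility 0.861. Per-patient control costs stay flat across
years (tariffs are constant), while total costs grow with the labelled
population. `run/outcomes.csv` has the full year × sex × age ×
measure table and `run/run_metadata.json` the config and parameter
version used.

The same pipeline is available as a library (`generate_fixture_inputs`,
`calibrate_all`, `run_simulation`, `aggregate_and_write`), which is what
the test suite exercises.

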