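"""Demographics: base-year population, births, mortality and net migration.

The simulated population is open: individuals enter through birth or net
immigration and exit through death, net emigration, or the end of the time
horizon.  The population is held as a pandas DataFrame with one row per
individual; all per-cycle operations are vectorised.

Scaled counts are rounded deterministically (half-up) rather than
stochastically so small-scale runs are exactly reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params_io import PopulationInputs

#: Columns of the individual-level population frame.
INDIVIDUAL_COLUMNS = {
    "id": np.int64,
    "sex": np.int8,
    "birth_year": np.int32,
    "age": np.int32,
    "fha": bool,
    "iae": np.int32,
    "has_asthma": bool,
    "onset_age": np.float64,  # NaN until first labelled
    "control_intercept": np.float64,  # NaN until first labelled
    "very_severe_history": np.int64,
}


def round_half_up(x) -> np.ndarray:
    """Deterministic half-up rounding of scaled counts."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


def make_individuals(sex, birth_year, age, start_id: int = 0) -> pd.DataFrame:
    """Assemble a population frame with demographic fields only; risk
    factors and asthma state are assigned by the other modules at entry."""
    sex = np.asarray(sex)
    n = len(sex)
    return pd.DataFrame(
        {
            "id": np.arange(start_id, start_id + n, dtype=np.int64),
            "sex": np.asarray(sex, dtype=np.int8),
            "birth_year": np.asarray(birth_year, dtype=np.int32),
            "age": np.asarray(age, dtype=np.int32),
            "fha": np.zeros(n, dtype=bool),
            "iae": np.zeros(n, dtype=np.int32),
            "has_asthma": np.zeros(n, dtype=bool),
            "onset_age": np.full(n, np.nan),
            "control_intercept": np.full(n, np.nan),
            "very_severe_history": np.zeros(n, dtype=np.int64),
        }
    )


def build_initial_population(
    year: int,
    scale: float,
    inputs: PopulationInputs,
    rng: np.random.Generator,
    start_id: int = 0,
) -> pd.DataFrame:
    """Instantiate round(scale x count) individuals for the base year, with
    (sex, age) drawn from the year's empirical distribution."""
    table = inputs.population[inputs.population["year"] == year]
    if table.empty:
        raise KeyError(f"population table has no rows for year {year}")
    counts = table["count"].to_numpy(dtype=float)
    total = round_half_up(scale * counts.sum())[()]
    if total == 0:
        return make_individuals([], [], [], start_id)
    probs = counts / counts.sum()
    idx = rng.choice(len(table), size=int(total), p=probs)
    sex = table["sex"].to_numpy()[idx]
    age = table["age"].to_numpy()[idx]
    return make_individuals(sex, year - age, age, start_id)


def sample_births(
    year: int,
    scenario: str,
    scale: float,
    inputs: PopulationInputs,
    rng: np.random.Generator,
    start_id: int = 0,
) -> pd.DataFrame:
    """Newborn cohort for one cycle: sexes Bernoulli(prob_male)."""
    rows = inputs.births[
        (inputs.births["year"] == year) & (inputs.births["scenario"] == scenario)
    ]
    if rows.empty:
        raise KeyError(f"no births row for year {year}, scenario {scenario!r}")
    births = float(rows["births"].iloc[0])
    p_male = float(rows["prob_male"].iloc[0])
    n = int(round_half_up(scale * births)[()])
    sex = (rng.random(n) < p_male).astype(np.int8)
    return make_individuals(sex, np.full(n, year), np.zeros(n, dtype=int), start_id)


class LifeTableLookup:
    """Dense (year, sex, age) -> death-probability array with age clamping."""

    def __init__(self, life: pd.DataFrame, mortality_adjustment: float = 1.0):
        self.year_min = int(life["year"].min())
        self.max_age = int(life["age"].max())
        n_years = int(life["year"].max()) - self.year_min + 1
        self.q = np.full((n_years, 2, self.max_age + 1), np.nan)
        self.q[
            life["year"].to_numpy() - self.year_min,
            life["sex"].to_numpy(),
            life["age"].to_numpy(),
        ] = life["p_death"].to_numpy()
        if mortality_adjustment != 1.0:
            self.q = np.clip(self.q * mortality_adjustment, 0.0, 1.0)

    def __call__(self, year, sex, age) -> np.ndarray:
        age = np.minimum(np.asarray(age), self.max_age)
        q = self.q[np.asarray(year) - self.year_min, np.asarray(sex), age]
        if np.isnan(q).any():
            raise KeyError("life table lookup hit a missing (year, sex, age) row")
        return q


def sample_deaths(
    pop: pd.DataFrame, year: int, life: LifeTableLookup, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli death flags for every individual this cycle."""
    q = life(year, pop["sex"].to_numpy(), pop["age"].to_numpy())
    return rng.random(len(pop)) < q


def sample_immigrants(
    year: int,
    scale: float,
    migration: pd.DataFrame,
    rng: np.random.Generator,
    start_id: int = 0,
) -> pd.DataFrame:
    """Instantiate this cycle's net immigrants.

    Per-stratum expected counts are scaled and rounded deterministically;
    (sex, age) follow the net-immigrant table exactly.
    """
    rows = migration[migration["year"] == year]
    n_per = round_half_up(scale * rows["net_immigrants"].to_numpy())
    sex = np.repeat(rows["sex"].to_numpy(), n_per)
    age = np.repeat(rows["age"].to_numpy(), n_per)
    return make_individuals(sex, year - age, age, start_id)


def sample_emigration(
    pop: pd.DataFrame, year: int, migration: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli emigration flags from the stratum probabilities."""
    rows = migration[migration["year"] == year]
    if rows.empty:
        return np.zeros(len(pop), dtype=bool)
    max_age = int(rows["age"].max())
    p = np.zeros((2, max_age + 1))
    p[rows["sex"].to_numpy(), rows["age"].to_numpy()] = rows[
        "emigration_prob"
    ].to_numpy()
    probs = p[pop["sex"].to_numpy(), np.minimum(pop["age"].to_numpy(), max_age)]
    return rng.random(len(pop)) < probs
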