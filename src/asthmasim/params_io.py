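"""Parameter tables, simulation configuration, and synthetic input fixtures.

Every coefficient and tariff the structural equations need is collected in a
:class:`ParameterSet` (validated with pydantic, serialised as a single JSON
document).  Demographic inputs — population counts, births, life tables and
optional net-migration tables — live in :class:`PopulationInputs` as pandas
DataFrames backed by plain CSV files.

Conventions used throughout the package
---------------------------------------
* Sex is binary and encoded as an integer: female = 0, male = 1.
* Ages are integer completed years, 0-based.  The maximum tabulated age is
  absorbing for lookups: any older age is clamped to the last row.
* Calendar years are integers; a cycle labelled ``Y`` covers ``[Y, Y + 1)``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

FEMALE = 0
MALE = 1
SEXES = (FEMALE, MALE)

#: Supported calendar range: earliest year with outcome-trend data through the
#: last year with population projections.
YEAR_MIN = 2001
YEAR_MAX = 2065

#: Last year with population *estimates*; later years use projections and a
#: base year beyond it triggers a fast-forward from here.
LAST_ESTIMATE_YEAR = 2019


class SimulationConfig(BaseModel):
    """Run-level settings for the annual-cycle microsimulation."""

    model_config = ConfigDict(extra="forbid")

    base_year: int = Field(default=2019, ge=YEAR_MIN, le=YEAR_MAX)
    horizon_end: int = Field(default=2030, ge=YEAR_MIN, le=YEAR_MAX)
    population_scale: float = Field(default=0.001, gt=0.0, le=1.0)
    projection_scenario: str = "medium"
    stabilisation_year: int = 2025
    min_asthma_age: int = Field(default=3, ge=0)
    mortality_adjustment: float = Field(default=1.0, gt=0.0)
    rng_seed: int = 0
    output_dir: str = "output"

    @model_validator(mode="after")
    def _ordered_years(self) -> "SimulationConfig":
        if self.horizon_end < self.base_year:
            raise ValueError("horizon_end must be >= base_year")
        return self


class AntibioticModel(BaseModel):
    """Negative-binomial model for courses of antibiotics in the first year
    of life.

    The log-mean is linear in sex and calendar year with a slope change at
    ``knot_year``; the year covariate enters centred at 2000.  The mean is
    floored at ``mean_floor`` (0.05 courses = 50 per 1,000 infants) so the
    declining time trend never extrapolates to implausibly low exposure.
    """

    model_config = ConfigDict(extra="forbid")

    beta0: float = 0.0
    beta1_sex: float = 0.0
    beta2_post2005: float = 0.0
    beta3_year: float = 0.0
    beta4_post2005_year: float = 0.0
    dispersion_theta: float = Field(default=1.0, gt=0.0)
    mean_floor: float = Field(default=0.05, gt=0.0)
    knot_year: int = 2005
    year_center: int = 2000


class EffectCoefficients(BaseModel):
    """Log-odds-ratio effects of the two modelled risk factors on asthma
    occurrence.

    Family history (FHA) contributes ``b0 + b1 * (min(age, cap) - floor)``
    from ``fha_age_floor`` (3) onward, with the age ramp capped at
    ``fha_age_cap`` (5).  Infant antibiotics (IAE) contribute
    ``b0 + b1 * (age - 3) + b2 * min(dose, dose_cap)`` inside the age window
    [3, 7] for any positive dose; doses above ``iae_dose_cap`` (3) count as 3.
    """

    model_config = ConfigDict(extra="forbid")

    fha_prev: tuple[float, float] = (0.0, 0.0)
    fha_inc: tuple[float, float] = (0.0, 0.0)
    iae_prev: tuple[float, float, float] = (0.0, 0.0, 0.0)
    iae_inc: tuple[float, float, float] = (0.0, 0.0, 0.0)
    fha_age_floor: int = 3
    fha_age_cap: int = 5
    iae_age_window: tuple[int, int] = (3, 7)
    iae_dose_cap: int = Field(default=3, ge=1)

    @model_validator(mode="after")
    def _window_ordered(self) -> "EffectCoefficients":
        lo, hi = self.iae_age_window
        if lo > hi:
            raise ValueError("iae_age_window bounds must be ordered")
        return self


#: Polynomial coding for the occurrence equations: raw centred powers.
#: year enters as (year - 2010) / 10, age as (age - 40) / 40.
OCC_YEAR_CENTER = 2010.0
OCC_YEAR_SCALE = 10.0
OCC_AGE_CENTER = 40.0
OCC_AGE_SCALE = 40.0

PREV_BETA_LEN = 34  # per sex: 2 year + 5 age + 10 year x age interactions
INC_BETA_LEN = 10  # per sex: 5 age terms


class OccurrenceCoefficients(BaseModel):
    """Logistic-regression coefficients for asthma prevalence and incidence.

    ``prev_beta`` holds 34 coefficients: for each sex (female block first),
    17 terms in the order year, year^2, age..age^5, year*age..year*age^5,
    year^2*age..year^2*age^5.  ``inc_beta`` holds 10: for each sex the 5 age
    polynomial terms.  Calendar year is clamped into
    [year_clamp_low, stabilisation year] before the polynomial expansion, so
    occurrence rates are flat before 2000 and after stabilisation.
    """

    model_config = ConfigDict(extra="forbid")

    prev_intercept: float = 0.0
    prev_beta: list[float] = Field(default_factory=lambda: [0.0] * PREV_BETA_LEN)
    inc_intercept: float = 0.0
    inc_year_slope: float = 0.0
    inc_beta: list[float] = Field(default_factory=lambda: [0.0] * INC_BETA_LEN)
    year_clamp_low: int = 2000
    #: Fallback label-retention probabilities when no calibrated reassessment
    #: table is supplied: children remit more often than adults.
    reassessment_keep_child: float = Field(default=0.95, ge=0.0, le=1.0)
    reassessment_keep_adult: float = Field(default=0.99, ge=0.0, le=1.0)
    reassessment_adult_age: int = 18

    @field_validator("prev_beta")
    @classmethod
    def _prev_len(cls, v: list[float]) -> list[float]:
        if len(v) != PREV_BETA_LEN:
            raise ValueError(f"prev_beta must have length {PREV_BETA_LEN}")
        return v

    @field_validator("inc_beta")
    @classmethod
    def _inc_len(cls, v: list[float]) -> list[float]:
        if len(v) != INC_BETA_LEN:
            raise ValueError(f"inc_beta must have length {INC_BETA_LEN}")
        return v


class ControlModel(BaseModel):
    """Random-intercept ordinal (proportional-odds) model for the fraction of
    a year spent uncontrolled / partially controlled / well-controlled.

    ``fixed_effects`` holds 4 coefficients: for each sex (female first) the
    age and age^2 terms, with age coded (age - 40)/40.  ``sigma`` is the
    standard deviation of the person-level intercept drawn once at first
    asthma labelling.
    """

    model_config = ConfigDict(extra="forbid")

    theta1: float = -1.4
    theta2: float = 0.2
    fixed_effects: list[float] = Field(default_factory=lambda: [0.0] * 4)
    sigma: float = Field(default=1.0, ge=0.0)

    @model_validator(mode="after")
    def _thresholds_ordered(self) -> "ControlModel":
        if not self.theta1 < self.theta2:
            raise ValueError("theta1 must be < theta2")
        return self

    @field_validator("fixed_effects")
    @classmethod
    def _fe_len(cls, v: list[float]) -> list[float]:
        if len(v) != 4:
            raise ValueError("fixed_effects must have length 4")
        return v


class ExacerbationModel(BaseModel):
    """Log-linear Poisson rate for annual exacerbation counts.

    The log-mean is a control-time-weighted combination of per-level log
    rates plus an additive calibration offset (default 0).  Default rates are
    0.564 (uncontrolled), 0.376 (partially controlled) and 0.188
    (well-controlled) events per person-year.
    """

    model_config = ConfigDict(extra="forbid")

    log_rate_uc: float = math.log(0.564)
    log_rate_pc: float = math.log(0.376)
    log_rate_wc: float = math.log(0.188)


class SeverityModel(BaseModel):
    """Dirichlet-multinomial split of exacerbations into mild / moderate /
    severe / very severe.

    A per-person-year probability vector is drawn from Dirichlet(``alpha``);
    for individuals with any past very severe exacerbations the very severe
    component is inflated by ``(1 + gamma) ** min(history, history_cap)`` and
    the vector renormalised.  The inflation form is this package's own
    documented construction.
    """

    model_config = ConfigDict(extra="forbid")

    alpha: tuple[float, float, float, float] = (3.2, 2.0, 0.6, 0.2)
    history_inflation_gamma: float = Field(default=0.25, ge=0.0)
    history_cap: int = Field(default=3, ge=1)

    @field_validator("alpha")
    @classmethod
    def _alpha_pos(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if any(a <= 0 for a in v):
            raise ValueError("alpha components must be positive")
        return v


def _default_adult_utilities(u18: float, max_age: int = 110) -> list[float]:
    # gentle linear decline with age, floored well above 0
    return [max(0.5, u18 - 0.0015 * (age - 18)) for age in range(18, max_age + 1)]


class PayoffTable(BaseModel):
    """Utility (QALY-weight) and direct-cost tariffs.

    Baseline utility is 1 at birth, linearly interpolated to the sex-specific
    age-18 value (0.881 female, 0.875 male), then follows the adult table
    (clamped at its oldest age).  Control disutilities are per full year at a
    level; exacerbation disutilities are full-year values pro-rated by the
    stated event duration (1 week mild, 2 weeks otherwise).  The severe
    tariffs are structurally tied to their neighbours: disutility is the
    midpoint, cost the geometric mean, of the moderate and very severe
    values.  Costs are annual/per-event amounts in ``currency_year`` dollars.
    """

    model_config = ConfigDict(extra="forbid")

    utility_at_18_female: float = 0.881
    utility_at_18_male: float = 0.875
    #: adult utilities for ages 18, 19, ... per sex; last entry absorbs older ages
    adult_utility_female: list[float] = Field(
        default_factory=lambda: _default_adult_utilities(0.881)
    )
    adult_utility_male: list[float] = Field(
        default_factory=lambda: _default_adult_utilities(0.875)
    )
    control_disutility: tuple[float, float, float] = (0.10, 0.09, 0.06)  # UC, PC, WC
    exac_disutility: tuple[float, float, float, float] = (0.32, 0.44, 0.50, 0.56)
    exac_duration_weeks: tuple[float, float, float, float] = (1.0, 2.0, 2.0, 2.0)
    control_cost: tuple[float, float, float] = (1700.0, 950.0, 550.0)  # UC, PC, WC
    exac_cost: tuple[float, float, float, float] = (
        130.0,
        580.0,
        math.sqrt(580.0 * 5400.0),
        5400.0,
    )
    currency_year: str = "2023 CAD"

    @model_validator(mode="after")
    def _structural_rules(self) -> "PayoffTable":
        if any(not (0.0 <= u <= 1.0) for u in (self.utility_at_18_female, self.utility_at_18_male)):
            raise ValueError("age-18 utilities must be in [0, 1]")
        for seq in (self.adult_utility_female, self.adult_utility_male):
            if not seq or any(not (0.0 <= u <= 1.0) for u in seq):
                raise ValueError("adult utilities must be non-empty and in [0, 1]")
        if any(d < 0 for d in self.control_disutility + self.exac_disutility):
            raise ValueError("disutilities must be non-negative")
        if any(c < 0 for c in self.control_cost + self.exac_cost):
            raise ValueError("costs must be non-negative")
        mild, moderate, severe, very_severe = self.exac_disutility
        if not math.isclose(severe, 0.5 * (moderate + very_severe), abs_tol=1e-9):
            raise ValueError("severe disutility must be the moderate/very-severe midpoint")
        _, c_mod, c_sev, c_vs = self.exac_cost
        if not math.isclose(c_sev, math.sqrt(c_mod * c_vs), rel_tol=1e-9):
            raise ValueError("severe cost must be the geometric mean of moderate and very severe")
        return self


class ParameterSet(BaseModel):
    """Every coefficient and tariff the five structural-equation groups need."""

    model_config = ConfigDict(extra="forbid")

    version: str = "synthetic-defaults-1"
    fha_probability: float = Field(default=0.293, ge=0.0, le=1.0)
    antibiotic_model: AntibioticModel = Field(default_factory=AntibioticModel)
    effect_coeffs: EffectCoefficients = Field(default_factory=EffectCoefficients)
    occurrence_coeffs: OccurrenceCoefficients = Field(default_factory=OccurrenceCoefficients)
    control_model: ControlModel = Field(default_factory=ControlModel)
    exacerbation_model: ExacerbationModel = Field(default_factory=ExacerbationModel)
    severity_model: SeverityModel = Field(default_factory=SeverityModel)
    payoffs: PayoffTable = Field(default_factory=PayoffTable)


def default_parameter_set() -> ParameterSet:
    """Shipped synthetic defaults.

    Scalar values the literature reports (family-history probability,
    per-control-level exacerbation rates, utilities, disutilities, durations,
    the antibiotic mean floor) are used directly; regression coefficients for
    which no public values exist are synthetic but chosen to produce
    epidemiologically plausible Canadian-like curves: childhood-peaked
    prevalence near 8-12%, childhood-peaked incidence of a few per 1,000,
    declining infant antibiotic prescribing that hits the floor in the 2030s.
    """
    prev_beta = [0.0] * PREV_BETA_LEN
    inc_beta = [0.0] * INC_BETA_LEN
    for s in SEXES:
        b = s * 17
        prev_beta[b + 0] = 0.15  # year: mild upward trend to 2025
        prev_beta[b + 1] = -0.05  # year^2: levelling off
        prev_beta[b + 2] = -0.55  # age: higher prevalence in childhood
        prev_beta[b + 3] = 0.35  # age^2
        prev_beta[b + 4] = 0.25  # age^3
        prev_beta[b + 7] = -0.04  # year x age
        ib = s * 5
        inc_beta[ib + 0] = -1.6  # incidence concentrated in childhood
        inc_beta[ib + 1] = 1.1
        inc_beta[ib + 2] = 0.9
    # slightly higher childhood prevalence among boys
    prev_beta[17 + 2] = -0.65
    return ParameterSet(
        antibiotic_model=AntibioticModel(
            beta0=math.log(0.85),
            beta1_sex=0.06,
            beta2_post2005=0.05,
            beta3_year=-0.02,
            beta4_post2005_year=-0.08,
            dispersion_theta=0.6,
        ),
        effect_coeffs=EffectCoefficients(
            fha_prev=(0.55, 0.06),
            fha_inc=(0.45, 0.05),
            iae_prev=(0.35, -0.06, 0.12),
            iae_inc=(0.30, -0.05, 0.10),
        ),
        occurrence_coeffs=OccurrenceCoefficients(
            prev_intercept=-2.35,
            prev_beta=prev_beta,
            inc_intercept=-5.0,
            inc_year_slope=-0.15,
            inc_beta=inc_beta,
        ),
        control_model=ControlModel(
            theta1=-1.4,
            theta2=0.2,
            fixed_effects=[0.10, 0.04, 0.16, 0.06],
            sigma=1.0,
        ),
    )


def save_parameter_set(params: ParameterSet, path: str | Path) -> Path:
    """Write a ParameterSet as a single JSON document."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(params.model_dump_json(indent=2))
    return path


def load_parameter_set(path: str | Path) -> ParameterSet:
    """Load and validate a ParameterSet; unknown keys are rejected."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"parameter file not found: {path}")
    return ParameterSet.model_validate_json(path.read_text())


# ---------------------------------------------------------------------------
# Population inputs
# ---------------------------------------------------------------------------

POPULATION_COLUMNS = ["year", "sex", "age", "count", "scenario"]
BIRTH_COLUMNS = ["year", "scenario", "births", "prob_male"]
LIFE_COLUMNS = ["year", "sex", "age", "p_death"]
MIGRATION_COLUMNS = ["year", "sex", "age", "net_immigrants", "emigration_prob"]


@dataclasses.dataclass
class PopulationInputs:
    """Demographic input tables.

    population: counts by year x sex x age (one scenario label per year;
    pre-2020 rows carry the estimate scenario label for every projection).
    births: total births and probability of male sex at birth by year.
    life: annual death probability by year x sex x age.
    migration: optional net-immigrant counts and emigration probabilities by
    year x sex x age; usually produced by :func:`calibration.calibrate_migration`.
    """

    population: pd.DataFrame
    births: pd.DataFrame
    life: pd.DataFrame
    migration: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def max_age(self) -> int:
        return int(self.population["age"].max())

    @property
    def years(self) -> list[int]:
        return sorted(self.population["year"].unique().tolist())

    def validate(self) -> None:
        for name, df, cols in [
            ("population", self.population, POPULATION_COLUMNS),
            ("births", self.births, BIRTH_COLUMNS),
            ("life", self.life, LIFE_COLUMNS),
        ]:
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValueError(f"{name} table missing columns {missing}")
        if (self.population["count"] < 0).any():
            raise ValueError("population counts must be non-negative")
        if ((self.births["births"] < 0) | ~self.births["prob_male"].between(0, 1)).any():
            raise ValueError("births must be >= 0 and prob_male in [0, 1]")
        if ~self.life["p_death"].between(0.0, 1.0).all():
            raise ValueError("death probabilities must lie in [0, 1]")
        ages = np.sort(self.population["age"].unique())
        if not np.array_equal(ages, np.arange(0, ages.max() + 1)):
            raise ValueError("population ages must be contiguous from 0")
        if self.migration is not None:
            missing = [c for c in MIGRATION_COLUMNS if c not in self.migration.columns]
            if missing:
                raise ValueError(f"migration table missing columns {missing}")
            if (self.migration["net_immigrants"] < 0).any():
                raise ValueError("net immigrant counts must be non-negative")
            if ~self.migration["emigration_prob"].between(0, 1).all():
                raise ValueError("emigration probabilities must lie in [0, 1]")

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.population.to_csv(directory / "population.csv", index=False)
        self.births.to_csv(directory / "births.csv", index=False)
        self.life.to_csv(directory / "life_table.csv", index=False)
        if self.migration is not None:
            self.migration.to_csv(directory / "migration.csv", index=False)
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "PopulationInputs":
        directory = Path(directory)
        for fname in ("population.csv", "births.csv", "life_table.csv"):
            if not (directory / fname).exists():
                raise FileNotFoundError(f"missing input table: {directory / fname}")
        migration = None
        if (directory / "migration.csv").exists():
            migration = pd.read_csv(directory / "migration.csv")
        return cls(
            population=pd.read_csv(directory / "population.csv"),
            births=pd.read_csv(directory / "births.csv"),
            life=pd.read_csv(directory / "life_table.csv"),
            migration=migration,
        )


def generate_fixture_inputs(
    seed: int = 0,
    max_age: int = 100,
    years: Sequence[int] | None = None,
    total_2019: float = 38_000_000.0,
    scenario: str = "medium",
) -> PopulationInputs:
    """Generate internally consistent synthetic demographic tables.

    The tables mimic the *shape* of national statistical-agency exports — a
    smooth population pyramid totalling ~38 million in 2019, Gompertz-like
    death probabilities that are monotone in age and reach 1 at ``max_age``,
    and births equal to the age-0 counts — without reproducing any real
    census values.  Deterministic given ``seed`` (the seed drives a small
    multiplicative jitter so distinct seeds give distinct but equally
    plausible tables).
    """
    if years is None:
        years = range(YEAR_MIN, YEAR_MAX + 1)
    years = list(years)
    if min(years) < YEAR_MIN or max(years) > YEAR_MAX:
        raise ValueError(f"fixture years must lie within {YEAR_MIN}-{YEAR_MAX}")
    rng = np.random.default_rng(seed)

    ages = np.arange(max_age + 1)
    # smooth pyramid: near-flat through mid-life, logistic roll-off in old age
    density = 1.0 / (1.0 + np.exp((ages - 62.0) / 11.0)) + 0.15 * np.exp(-ages / 25.0)
    density /= density.sum()
    male_frac = np.clip(0.512 - 0.0022 * ages, 0.30, 0.52)

    pop_rows = []
    birth_rows = []
    life_rows = []
    for year in years:
        total = total_2019 * 1.01 ** (year - 2019)
        jitter = 1.0 + 0.005 * rng.standard_normal(max_age + 1)
        counts_all = total * density * np.clip(jitter, 0.9, 1.1)
        for sex in SEXES:
            frac = male_frac if sex == MALE else 1.0 - male_frac
            counts = np.round(counts_all * frac)
            pop_rows.append(
                pd.DataFrame(
                    {
                        "year": year,
                        "sex": sex,
                        "age": ages,
                        "count": counts,
                        "scenario": scenario,
                    }
                )
            )
            q = 3.0e-4 + 2.2e-5 * np.exp(0.095 * ages)
            q *= (1.25 if sex == MALE else 1.0) * 0.998 ** (year - YEAR_MIN)
            q = np.clip(q, 0.0, 1.0)
            q[-1] = 1.0  # oldest tabulated age is absorbing
            life_rows.append(
                pd.DataFrame({"year": year, "sex": sex, "age": ages, "p_death": q})
            )
        age0 = sum(df["count"].iloc[0] for df in pop_rows[-2:])
        male0 = pop_rows[-1]["count"].iloc[0]
        birth_rows.append(
            {
                "year": year,
                "scenario": scenario,
                "births": float(age0),
                "prob_male": float(male0 / age0) if age0 > 0 else 0.5,
            }
        )

    return PopulationInputs(
        population=pd.concat(pop_rows, ignore_index=True),
        births=pd.DataFrame(birth_rows),
        life=pd.concat(life_rows, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# Coverage validation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CoverageReport:
    """Report of missing table rows for a planned run (report-only)."""

    gaps: list[dict]
    simulated_years: list[int]

    @property
    def ok(self) -> bool:
        return not self.gaps

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.gaps, columns=["table", "year", "detail"])


def simulated_year_range(config: SimulationConfig) -> list[int]:
    """Years the engine will touch, including any silent fast-forward from
    the last population-estimate year to a later base year."""
    start = config.base_year
    if config.base_year > LAST_ESTIMATE_YEAR:
        start = LAST_ESTIMATE_YEAR
    return list(range(start, config.horizon_end + 1))


def validate_coverage(
    config: SimulationConfig,
    inputs: PopulationInputs,
    params: ParameterSet | None = None,
) -> CoverageReport:
    """Confirm every year the engine will touch has rows in each table."""
    years = simulated_year_range(config)
    gaps: list[dict] = []

    pop_years = set(inputs.population["year"].unique())
    init_year = years[0]
    if init_year not in pop_years:
        gaps.append(
            {"table": "population", "year": init_year, "detail": "initial population year missing"}
        )

    birth_ok = inputs.births[inputs.births["scenario"] == config.projection_scenario]
    birth_years = set(birth_ok["year"].unique())
    life_by_year = inputs.life.groupby("year").size()
    expected_life_rows = 2 * (inputs.max_age + 1)
    for year in years[1:]:
        if year not in birth_years:
            gaps.append(
                {
                    "table": "births",
                    "year": year,
                    "detail": f"no births row for scenario {config.projection_scenario!r}",
                }
            )
    for year in years:
        n = int(life_by_year.get(year, 0))
        if n < expected_life_rows:
            gaps.append(
                {
                    "table": "life",
                    "year": year,
                    "detail": f"{n}/{expected_life_rows} sex-age rows present",
                }
            )
    if inputs.migration is not None:
        mig_years = set(inputs.migration["year"].unique())
        for year in years[1:]:
            if year not in mig_years:
                gaps.append(
                    {"table": "migration", "year": year, "detail": "no migration rows"}
                )
    return CoverageReport(gaps=gaps, simulated_years=years)
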