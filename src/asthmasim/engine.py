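"""Annual-cycle simulation loop and output aggregation.

Within-cycle event order (fixed so runs are exactly reproducible):

1. age increment (existing residents)
2. births enter
3. net immigrants enter (receiving risk factors and prevalence-based labels)
4. incidence (unlabelled) / reassessment (labelled)
5. control intercepts for newly labelled individuals
6. control proportions -> exacerbations -> severity split
7. payoffs accrue (in full, including for those who exit this cycle)
8. deaths
9. emigration

Randomness is split into four independent substreams (demography, risk
factors, occurrence, outcomes) spawned from the run seed, so switching one
module's behaviour does not perturb another's draws.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import demographics, occurrence, outcomes, payoffs, risk_factors
from .calibration import CalibrationResult
from .params_io import (
    LAST_ESTIMATE_YEAR,
    ParameterSet,
    PopulationInputs,
    SimulationConfig,
    simulated_year_range,
    validate_coverage,
)

STRATUM_MEASURES = [
    "population",
    "births",
    "immigrants",
    "deaths",
    "emigrants",
    "asthma_count",
    "incident",
    "remissions",
    "ct_uc",
    "ct_pc",
    "ct_wc",
    "exac_mild",
    "exac_moderate",
    "exac_severe",
    "exac_very_severe",
    "qalys",
    "cost_control",
    "cost_exac",
]


@dataclasses.dataclass
class AnnualOutcomes:
    """Aggregated year x sex x age results of one run."""

    strata: pd.DataFrame  # tidy: year, sex, age + STRATUM_MEASURES

    def totals_by_sex(self) -> pd.DataFrame:
        return self.strata.groupby(["year", "sex"], as_index=False)[
            STRATUM_MEASURES
        ].sum()

    def summary(self) -> pd.DataFrame:
        """Per year x sex: prevalence per 1,000, mean per-patient costs and
        mean utility per person."""
        t = self.totals_by_sex()
        t["prevalence_per_1000"] = 1000.0 * t["asthma_count"] / t["population"]
        with np.errstate(invalid="ignore", divide="ignore"):
            t["cost_control_per_patient"] = t["cost_control"] / t["asthma_count"]
            t["cost_exac_per_patient"] = t["cost_exac"] / t["asthma_count"]
        t["mean_utility"] = t["qalys"] / t["population"]
        return t[
            [
                "year",
                "sex",
                "population",
                "asthma_count",
                "prevalence_per_1000",
                "cost_control_per_patient",
                "cost_exac_per_patient",
                "mean_utility",
            ]
        ]

    def conservation_errors(self) -> pd.DataFrame:
        """Per-sex check of pop(Y+1) = pop(Y) + births(Y+1) + immigrants(Y+1)
        - deaths(Y) - emigrants(Y); the error column should be exactly 0."""
        t = self.totals_by_sex().sort_values(["sex", "year"])
        rows = []
        for sex, g in t.groupby("sex"):
            g = g.reset_index(drop=True)
            for i in range(1, len(g)):
                expected = (
                    g.loc[i - 1, "population"]
                    - g.loc[i - 1, "deaths"]
                    - g.loc[i - 1, "emigrants"]
                    + g.loc[i, "births"]
                    + g.loc[i, "immigrants"]
                )
                rows.append(
                    {
                        "year": int(g.loc[i, "year"]),
                        "sex": sex,
                        "error": float(g.loc[i, "population"] - expected),
                    }
                )
        return pd.DataFrame(rows, columns=["year", "sex", "error"])


class TableLookup:
    """Dense (year, sex, age) -> value lookup with clamping and a default."""

    def __init__(
        self, table: pd.DataFrame | None, value_col: str, default: float = 0.0
    ):
        self.default = default
        self.table = None
        if table is not None and len(table):
            self.year_min = int(table["year"].min())
            self.year_max = int(table["year"].max())
            self.age_max = int(table["age"].max())
            arr = np.full(
                (self.year_max - self.year_min + 1, 2, self.age_max + 1), default
            )
            arr[
                table["year"].to_numpy() - self.year_min,
                table["sex"].to_numpy(),
                table["age"].to_numpy(),
            ] = table[value_col].to_numpy()
            self.table = arr

    def __call__(self, year, sex, age):
        sex = np.asarray(sex)
        if self.table is None:
            return np.full(sex.shape, self.default)
        y = np.clip(np.asarray(year), self.year_min, self.year_max) - self.year_min
        a = np.clip(np.asarray(age), 0, self.age_max)
        return self.table[y, sex, a]


class _Engine:
    def __init__(
        self,
        config: SimulationConfig,
        inputs: PopulationInputs,
        params: ParameterSet,
        calib: CalibrationResult | None,
    ):
        self.config = config
        self.inputs = inputs
        self.params = params
        self.calib = calib
        streams = np.random.SeedSequence(config.rng_seed).spawn(4)
        self.rng_demo, self.rng_risk, self.rng_occ, self.rng_out = (
            np.random.default_rng(s) for s in streams
        )
        self.life = demographics.LifeTableLookup(
            inputs.life, config.mortality_adjustment
        )
        self.migration = None
        if calib is not None and calib.migration is not None:
            self.migration = calib.migration
        elif inputs.migration is not None:
            self.migration = inputs.migration
        self.keep_lookup = TableLookup(
            calib.reassessment if calib is not None else None, "keep_prob", default=1.0
        )
        self.has_keep_table = (
            calib is not None and calib.reassessment is not None
        )
        occ = calib.occurrence_offsets if calib is not None else None
        self.prev_offset = TableLookup(occ, "delta_prev", 0.0)
        self.inc_offset = TableLookup(occ, "delta_inc", 0.0)
        self.exac_offset = TableLookup(
            calib.exacerbation_offsets if calib is not None else None, "offset", 0.0
        )
        self.next_id = 0
        self.records: list[pd.DataFrame] = []

    # -- helpers ----------------------------------------------------------

    def _take_ids(self, n: int) -> int:
        start = self.next_id
        self.next_id += n
        return start

    def assign_risk_factors(self, pop: pd.DataFrame) -> None:
        n = len(pop)
        if n == 0:
            return
        pop["fha"] = risk_factors.assign_family_history(
            self.params.fha_probability, self.rng_risk, n
        )
        mu = risk_factors.antibiotic_mean(
            pop["sex"].to_numpy(), pop["birth_year"].to_numpy(), self.params.antibiotic_model
        )
        pop["iae"] = risk_factors.sample_antibiotic_courses(
            mu, self.params.antibiotic_model.dispersion_theta, self.rng_risk
        ).astype(np.int32)

    def assign_prevalent_labels(self, pop: pd.DataFrame, year: int) -> None:
        """Prevalence-equation labels for entrants, with onset-history and
        control-intercept initialisation for those labelled."""
        n = len(pop)
        if n == 0:
            return
        sex = pop["sex"].to_numpy()
        age = pop["age"].to_numpy()
        p = occurrence.prevalence_probability(
            year,
            sex,
            age,
            pop["fha"].to_numpy(),
            pop["iae"].to_numpy(),
            self.params.occurrence_coeffs,
            self.params.effect_coeffs,
            self.config.min_asthma_age,
            self.config.stabilisation_year,
            offset=self.prev_offset(year, sex, age),
        )
        labelled = self.rng_occ.random(n) < p
        idx = np.flatnonzero(labelled)
        if len(idx) == 0:
            return
        pop.iloc[
            idx, pop.columns.get_loc("has_asthma")
        ] = True
        # onset age uniform between the minimum asthma age and current age
        lo = self.config.min_asthma_age
        onset = lo + np.floor(
            self.rng_out.random(len(idx)) * (age[idx] - lo + 1)
        )
        pop.iloc[idx, pop.columns.get_loc("onset_age")] = onset
        # past very severe exacerbations: Poisson in years since onset at the
        # baseline very severe rate (documented stand-in initialisation)
        alpha = np.asarray(self.params.severity_model.alpha)
        ct0 = outcomes.control_proportions(
            sex[idx], age[idx], 0.0, self.params.control_model
        )
        base_rate = outcomes.exacerbation_mean(
            ct0, 0.0, self.params.exacerbation_model
        ) * (alpha[3] / alpha.sum())
        vsh = self.rng_out.poisson(base_rate * (age[idx] - onset))
        pop.iloc[idx, pop.columns.get_loc("very_severe_history")] = vsh
        pop.iloc[
            idx, pop.columns.get_loc("control_intercept")
        ] = outcomes.draw_control_intercept(
            self.params.control_model.sigma, self.rng_out, len(idx)
        )

    def keep_probabilities(self, year: int, sex: np.ndarray, age: np.ndarray):
        if self.has_keep_table:
            return self.keep_lookup(year, sex, age)
        oc = self.params.occurrence_coeffs
        return np.where(
            age >= oc.reassessment_adult_age,
            oc.reassessment_keep_adult,
            oc.reassessment_keep_child,
        )

    # -- the loop ---------------------------------------------------------

    def run(self) -> AnnualOutcomes:
        cfg = self.config
        report = validate_coverage(cfg, self.inputs, self.params)
        if not report.ok:
            raise ValueError(
                "input tables do not cover the planned run:\n"
                + report.to_frame().to_string(index=False)
            )
        years = report.simulated_years
        pop = demographics.build_initial_population(
            years[0], cfg.population_scale, self.inputs, self.rng_demo
        )
        self.next_id = len(pop)
        self.assign_risk_factors(pop)
        self.assign_prevalent_labels(pop, years[0])

        for i, year in enumerate(years):
            n_births = n_immigrants = 0
            entered = None
            if i > 0:
                pop["age"] += 1
                newborns = demographics.sample_births(
                    year,
                    cfg.projection_scenario,
                    cfg.population_scale,
                    self.inputs,
                    self.rng_demo,
                    self._take_ids(0),
                )
                self.next_id += len(newborns)
                self.assign_risk_factors(newborns)
                n_births = len(newborns)
                immigrants = None
                if self.migration is not None:
                    immigrants = demographics.sample_immigrants(
                        year,
                        cfg.population_scale,
                        self.migration,
                        self.rng_demo,
                        self._take_ids(0),
                    )
                    self.next_id += len(immigrants)
                    self.assign_risk_factors(immigrants)
                    self.assign_prevalent_labels(immigrants, year)
                    n_immigrants = len(immigrants)
                frames = [pop, newborns] + (
                    [immigrants] if immigrants is not None else []
                )
                entered = pd.concat(frames, ignore_index=True)
                pop = entered
                entry_flag = np.zeros(len(pop), dtype=np.int8)
                entry_flag[len(pop) - n_immigrants - n_births : len(pop) - n_immigrants] = 1
                entry_flag[len(pop) - n_immigrants :] = 2
            else:
                entry_flag = np.zeros(len(pop), dtype=np.int8)

            sex = pop["sex"].to_numpy()
            age = pop["age"].to_numpy()
            incident = np.zeros(len(pop), dtype=bool)
            remitted = np.zeros(len(pop), dtype=bool)
            if i > 0:
                labelled = pop["has_asthma"].to_numpy()
                # entrants this cycle already carry prevalence-equation labels
                resident = entry_flag == 0
                eligible = resident & ~labelled & (age >= cfg.min_asthma_age)
                p_inc = occurrence.incidence_probability(
                    year,
                    sex,
                    age,
                    pop["fha"].to_numpy(),
                    pop["iae"].to_numpy(),
                    self.params.occurrence_coeffs,
                    self.params.effect_coeffs,
                    cfg.min_asthma_age,
                    cfg.stabilisation_year,
                    offset=self.inc_offset(year, sex, age),
                )
                incident = eligible & (self.rng_occ.random(len(pop)) < p_inc)
                keep = occurrence.reassess_label(
                    self.keep_probabilities(year, sex, age), self.rng_occ
                )
                remitted = resident & labelled & ~keep
                pop.loc[incident, "has_asthma"] = True
                pop.loc[incident, "onset_age"] = age[incident]
                pop.loc[remitted, "has_asthma"] = False
                # intercepts: new labels draw once; relabelled keep theirs
                need = incident & pop["control_intercept"].isna().to_numpy()
                pop.loc[need, "control_intercept"] = outcomes.draw_control_intercept(
                    self.params.control_model.sigma, self.rng_out, int(need.sum())
                )

            labelled = pop["has_asthma"].to_numpy()
            lab_idx = np.flatnonzero(labelled)
            ct = np.zeros((len(pop), 3))
            sev_counts = np.zeros((len(pop), 4), dtype=np.int64)
            if len(lab_idx):
                ct[lab_idx] = outcomes.control_proportions(
                    sex[lab_idx],
                    age[lab_idx],
                    pop["control_intercept"].to_numpy()[lab_idx],
                    self.params.control_model,
                )
                mean = outcomes.exacerbation_mean(
                    ct[lab_idx],
                    self.exac_offset(year, sex[lab_idx], age[lab_idx]),
                    self.params.exacerbation_model,
                )
                n_ex = outcomes.sample_exacerbations(mean, self.rng_out)
                w = outcomes.severity_weights(
                    self.params.severity_model,
                    pop["very_severe_history"].to_numpy()[lab_idx],
                    self.rng_out,
                )
                sev_counts[lab_idx] = outcomes.sample_severity_counts(
                    n_ex, w, self.rng_out
                )
                pop.loc[pop.index[lab_idx], "very_severe_history"] = (
                    pop["very_severe_history"].to_numpy()[lab_idx]
                    + sev_counts[lab_idx, 3]
                )

            utility = payoffs.person_year_utility(
                sex, age, labelled, ct, sev_counts, self.params.payoffs
            )
            cost_control = np.where(
                labelled, ct @ np.asarray(self.params.payoffs.control_cost), 0.0
            )
            cost_exac = np.where(
                labelled, sev_counts @ np.asarray(self.params.payoffs.exac_cost), 0.0
            )

            died = demographics.sample_deaths(pop, year, self.life, self.rng_demo)
            emigrated = np.zeros(len(pop), dtype=bool)
            if self.migration is not None:
                emigrated = demographics.sample_emigration(
                    pop, year, self.migration, self.rng_demo
                ) & ~died

            if year >= cfg.base_year:
                frame = pd.DataFrame(
                    {
                        "year": year,
                        "sex": sex,
                        "age": age,
                        "population": 1,
                        "births": (entry_flag == 1).astype(int),
                        "immigrants": (entry_flag == 2).astype(int),
                        "deaths": died.astype(int),
                        "emigrants": emigrated.astype(int),
                        "asthma_count": labelled.astype(int),
                        "incident": incident.astype(int),
                        "remissions": remitted.astype(int),
                        "ct_uc": ct[:, 0] * labelled,
                        "ct_pc": ct[:, 1] * labelled,
                        "ct_wc": ct[:, 2] * labelled,
                        "exac_mild": sev_counts[:, 0],
                        "exac_moderate": sev_counts[:, 1],
                        "exac_severe": sev_counts[:, 2],
                        "exac_very_severe": sev_counts[:, 3],
                        "qalys": utility,
                        "cost_control": cost_control,
                        "cost_exac": cost_exac,
                    }
                )
                self.records.append(
                    frame.groupby(["year", "sex", "age"], as_index=False).sum()
                )

            pop = pop.loc[~died & ~emigrated].reset_index(drop=True)

        strata = (
            pd.concat(self.records, ignore_index=True)
            if self.records
            else pd.DataFrame(columns=["year", "sex", "age"] + STRATUM_MEASURES)
        )
        return AnnualOutcomes(strata=strata)


def run_simulation(
    config: SimulationConfig,
    inputs: PopulationInputs,
    params: ParameterSet,
    calib: CalibrationResult | None = None,
) -> AnnualOutcomes:
    """Run the full open-population microsimulation.

    If ``config.base_year`` is later than the last population-estimate year
    (2019), the engine silently simulates from 2019 to the base year and
    records outputs from the base year onward.  Deterministic for a fixed
    ``config.rng_seed``.
    """
    return _Engine(config, inputs, params, calib).run()


def aggregate_and_write(
    outcomes_: AnnualOutcomes,
    output_dir: str | Path,
    config: SimulationConfig | None = None,
    params: ParameterSet | None = None,
) -> dict[str, Path]:
    """Write tidy per-stratum outcomes, a per-year summary, and run metadata."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "outcomes": output_dir / "outcomes.csv",
        "summary": output_dir / "summary.csv",
        "metadata": output_dir / "run_metadata.json",
    }
    cols = ["year", "sex", "age"] + STRATUM_MEASURES
    strata = outcomes_.strata.reindex(columns=cols)
    strata.to_csv(paths["outcomes"], index=False)
    outcomes_.summary().to_csv(paths["summary"], index=False)
    meta = {
        "config": config.model_dump() if config is not None else None,
        "parameter_version": params.version if params is not None else None,
    }
    paths["metadata"].write_text(json.dumps(meta, indent=2, default=str))
    return paths
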