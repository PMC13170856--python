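"""Calibration: solve the correction terms the structural equations leave free.

Four quantities are not estimated from data but solved so that simulated
marginals hit their targets (a reconstructed procedure, documented in the
methods note):

* **Net migration** — deterministic survivor accounting between consecutive
  population-table years; surpluses become immigrant counts, deficits become
  emigration probabilities.
* **Occurrence intercept offsets** — an additive logit correction per
  (year, sex, age) so that the risk-factor-marginal prevalence/incidence
  equals the crude target, solved by bracketed monotone root-finding.
* **Reassessment keep-probabilities** — cohort accounting linking
  consecutive prevalence targets and incidence, clamped into [0, 1].
* **Exacerbation intercept offset** — a log-scale correction matching a
  target very-severe exacerbation rate, estimated by simulation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import nbinom

from . import occurrence, outcomes, risk_factors
from .params_io import (
    ControlModel,
    ExacerbationModel,
    ParameterSet,
    PopulationInputs,
    SeverityModel,
    SEXES,
)

ROOT_TOL = 1e-10
ROOT_BRACKET = 50.0


@dataclasses.dataclass
class CalibrationResult:
    """Solved correction terms plus achieved-vs-target diagnostics."""

    migration: pd.DataFrame | None = None
    reassessment: pd.DataFrame | None = None
    occurrence_offsets: pd.DataFrame | None = None
    exacerbation_offsets: pd.DataFrame | None = None
    diagnostics: pd.DataFrame | None = None

    label: str = "reconstructed procedure"

    _FILES = {
        "migration": "migration.csv",
        "reassessment": "reassessment.csv",
        "occurrence_offsets": "occurrence_offsets.csv",
        "exacerbation_offsets": "exacerbation_offsets.csv",
        "diagnostics": "diagnostics.csv",
    }

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for attr, fname in self._FILES.items():
            df = getattr(self, attr)
            if df is not None:
                df.to_csv(directory / fname, index=False)
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "CalibrationResult":
        directory = Path(directory)
        kwargs = {}
        for attr, fname in cls._FILES.items():
            path = directory / fname
            if path.exists():
                kwargs[attr] = pd.read_csv(path)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Net migration
# ---------------------------------------------------------------------------


def calibrate_migration(
    inputs: PopulationInputs,
    years: list[int] | None = None,
    scenario: str | None = None,
) -> pd.DataFrame:
    """Deterministic net-migration accounting between consecutive years.

    For each transition Y -> Y+1 and stratum (sex, age): the expected count
    absent migration is last year's count thinned by the life table (ages
    >= 1; the oldest age pools its own survivors with those ageing in) or
    the birth cohort (age 0).  A positive shortfall of the target over the
    expectation becomes a net-immigrant count at (Y+1, sex, age); a surplus
    becomes an emigration probability applied to stratum (Y, sex, age-1)
    at the end of cycle Y.

    Raises if any required emigration probability exceeds 1.
    """
    if years is None:
        years = inputs.years
    years = sorted(years)
    max_age = inputs.max_age
    pop = inputs.population
    if scenario is not None:
        pop = pop[pop["scenario"] == scenario]

    P = np.zeros((len(years), 2, max_age + 1))
    for i, y in enumerate(years):
        rows = pop[pop["year"] == y]
        P[i, rows["sex"].to_numpy(), rows["age"].to_numpy()] = rows["count"].to_numpy()

    Q = np.zeros_like(P)
    for i, y in enumerate(years):
        rows = inputs.life[inputs.life["year"] == y]
        Q[i, rows["sex"].to_numpy(), np.minimum(rows["age"].to_numpy(), max_age)] = rows[
            "p_death"
        ].to_numpy()

    births = inputs.births
    if scenario is not None:
        births = births[births["scenario"] == scenario]
    births = births.set_index("year")

    imm_rows: list[dict] = []
    emi_rows: list[dict] = []
    for i in range(len(years) - 1):
        y, y1 = years[i], years[i + 1]
        if y1 != y + 1:
            raise ValueError("population years must be consecutive for calibration")
        surv = P[i] * (1.0 - Q[i])
        expected = np.zeros((2, max_age + 1))
        expected[:, 1:] = surv[:, :-1]
        expected[:, max_age] += surv[:, max_age]  # oldest age is absorbing
        if y1 in births.index:
            b = float(births.loc[y1, "births"])
            pm = float(births.loc[y1, "prob_male"])
            expected[0, 0] = b * (1.0 - pm)
            expected[1, 0] = b * pm
        flow = P[i + 1] - expected
        for sex in SEXES:
            for age in range(max_age + 1):
                f = flow[sex, age]
                if f >= 0:
                    if f > 0:
                        imm_rows.append(
                            {"year": y1, "sex": sex, "age": age, "net_immigrants": f}
                        )
                else:
                    src_age = max(age - 1, 0)
                    base = surv[sex, src_age] if age >= 1 else expected[sex, 0]
                    if base <= 0:
                        raise ValueError(
                            f"cannot emigrate from empty stratum year={y} sex={sex} age={src_age}"
                        )
                    prob = -f / base
                    if prob > 1.0 + 1e-9:
                        raise ValueError(
                            f"infeasible emigration probability {prob:.3f} for "
                            f"year={y} sex={sex} age={src_age}"
                        )
                    emi_rows.append(
                        {
                            "year": y if age >= 1 else y1,
                            "sex": sex,
                            "age": src_age if age >= 1 else 0,
                            "emigration_prob": min(prob, 1.0),
                        }
                    )
    imm = pd.DataFrame(imm_rows, columns=["year", "sex", "age", "net_immigrants"])
    emi = pd.DataFrame(emi_rows, columns=["year", "sex", "age", "emigration_prob"])
    emi = emi.groupby(["year", "sex", "age"], as_index=False)["emigration_prob"].max()
    out = imm.merge(emi, on=["year", "sex", "age"], how="outer")
    for col in ("net_immigrants", "emigration_prob"):
        out[col] = out[col].astype(float).fillna(0.0)
    return out.sort_values(["year", "sex", "age"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Occurrence intercept offsets
# ---------------------------------------------------------------------------


def risk_cell_distribution(
    sex: int, birth_year: int, params: ParameterSet
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint distribution of (FHA flag, capped IAE dose) for one birth cohort.

    Returns (fha, dose, weight) arrays over the 2 x (cap+1) cells; doses at
    or above the cap are pooled (the occurrence effect saturates there).
    """
    cap = params.effect_coeffs.iae_dose_cap
    mu = risk_factors.antibiotic_mean(sex, birth_year, params.antibiotic_model)
    theta = params.antibiotic_model.dispersion_theta
    p = theta / (theta + mu)
    dose_probs = np.append(
        nbinom.pmf(np.arange(cap), theta, p), nbinom.sf(cap - 1, theta, p)
    )
    pf = params.fha_probability
    fha = np.repeat([0, 1], cap + 1)
    dose = np.tile(np.arange(cap + 1), 2)
    weight = np.concatenate([(1 - pf) * dose_probs, pf * dose_probs])
    return fha, dose, weight


def solve_logit_offset(target: float, eta_cells: np.ndarray, weights: np.ndarray) -> float:
    """Solve delta so that sum_i w_i * invlogit(eta_i + delta) = target.

    The left side is strictly increasing in delta, so a bracketed root is
    unique; solved to 1e-10.
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target probability must lie strictly inside (0, 1)")
    weights = weights / weights.sum()

    def g(delta: float) -> float:
        return float(weights @ expit(eta_cells + delta) - target)

    lo, hi = -ROOT_BRACKET, ROOT_BRACKET
    if g(lo) > 0 or g(hi) < 0:
        raise ValueError("target marginal outside the attainable range")
    return float(brentq(g, lo, hi, xtol=ROOT_TOL))


def calibrate_occurrence_offsets(
    params: ParameterSet,
    years: list[int],
    max_age: int,
    min_asthma_age: int = 3,
    stabilisation_year: int = 2025,
    inc_targets: dict[tuple[int, int, int], float] | None = None,
) -> pd.DataFrame:
    """Additive logit corrections aligning risk-factor-marginal occurrence
    with its targets.

    The prevalence target for each (year, sex, age) cell is the crude base
    equation (no risk-factor terms); the incidence target is either the
    crude base equation or, when ``inc_targets`` supplies a value for the
    cell (from the cohort accounting in :func:`calibrate_reassessment`),
    that value.  Each offset re-centres its equation so that averaging over
    the cohort's joint (FHA, IAE) distribution reproduces the target.
    """
    rows = []
    cell_cache: dict[tuple[int, int], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    inc_targets = inc_targets or {}
    for year in years:
        for sex in SEXES:
            for age in range(min_asthma_age, max_age + 1):
                key = (sex, year - age)
                if key not in cell_cache:
                    cell_cache[key] = risk_cell_distribution(sex, year - age, params)
                fha, dose, w = cell_cache[key]
                rec = {"year": year, "sex": sex, "age": age}

                eta_prev = occurrence.prevalence_linear_predictor(
                    year, sex, age, params.occurrence_coeffs, stabilisation_year
                )
                target_prev = float(expit(eta_prev))
                eff_prev = occurrence.fha_log_or(
                    fha, age, params.effect_coeffs, "prev"
                ) + occurrence.iae_log_or(dose, age, params.effect_coeffs, "prev")
                delta_prev = solve_logit_offset(target_prev, eta_prev + eff_prev, w)
                p_cell = expit(eta_prev + eff_prev + delta_prev)
                rec["delta_prev"] = delta_prev
                rec["target_prev"] = target_prev
                rec["achieved_prev"] = float((w / w.sum()) @ p_cell)

                eta_inc = occurrence.incidence_linear_predictor(
                    year, sex, age, params.occurrence_coeffs, stabilisation_year
                )
                target_inc = inc_targets.get((year, sex, age), float(expit(eta_inc)))
                eff_inc = occurrence.fha_log_or(
                    fha, age, params.effect_coeffs, "inc"
                ) + occurrence.iae_log_or(dose, age, params.effect_coeffs, "inc")
                # incidence acts on the unlabelled pool, which is depleted of
                # high-risk cells; weight cells by 1 - P(labelled | cell)
                w_unlab = w * (1.0 - p_cell)
                if target_inc <= 0.0 or w_unlab.sum() <= 0.0:
                    rec["delta_inc"] = 0.0
                    rec["target_inc"] = target_inc
                    rec["achieved_inc"] = float("nan")
                else:
                    delta_inc = solve_logit_offset(target_inc, eta_inc + eff_inc, w_unlab)
                    rec["delta_inc"] = delta_inc
                    rec["target_inc"] = target_inc
                    rec["achieved_inc"] = float(
                        (w_unlab / w_unlab.sum()) @ expit(eta_inc + eff_inc + delta_inc)
                    )
                rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reassessment keep-probabilities
# ---------------------------------------------------------------------------


def calibrate_reassessment(
    prev_fn,
    inc_fn,
    years: list[int],
    max_age: int,
    min_asthma_age: int = 3,
) -> pd.DataFrame:
    """Cohort-accounting solve for label retention and calibrated incidence.

    Following one cohort from (Y, age) to (Y+1, age+1), the labelled
    fraction evolves as ``p1 = p0 * keep + (1 - p0) * inc``, where ``keep``
    and ``inc`` act in cycle Y+1.  Given target prevalences ``p0``/``p1``
    (from ``prev_fn(year, sex, age)``) and the crude incidence
    ``inc_fn(year, sex, age)``, the solve prefers the crude incidence:

    * ``keep = (p1 - (1 - p0) * inc) / p0`` when that lies in [0, 1];
    * if keep would exceed 1 (incidence too small to sustain the target),
      keep is clamped to 1 and the required incidence
      ``(p1 - p0) / (1 - p0)`` is recorded as ``inc_target``;
    * if keep would fall below 0 (prevalence collapsing faster than full
      remission), keep is clamped to 0 and ``inc_target = p1 / (1 - p0)``.

    Rows are keyed at the *destination* cell (Y+1, sex, age+1) — the cell at
    which the engine looks the probabilities up.  ``clamped`` records which
    cells needed an incidence adjustment.  Mortality is assumed
    label-independent, so it cancels from the labelled fraction.
    """
    rows = []
    for year in years[:-1]:
        for sex in SEXES:
            for age in range(min_asthma_age - 1, max_age):
                p0 = prev_fn(year, sex, age) if age >= min_asthma_age else 0.0
                p1 = prev_fn(year + 1, sex, age + 1)
                inc = inc_fn(year + 1, sex, age + 1)
                if p1 <= 0.0:
                    continue
                if p0 > 0.0:
                    keep = (p1 - (1.0 - p0) * inc) / p0
                else:
                    keep = 1.0
                clamped = False
                if keep > 1.0 or p0 == 0.0:
                    # p0 == 0 seeds a fresh cohort (not a clamp): the label
                    # can only arrive through incidence
                    clamped = keep > 1.0
                    keep = 1.0
                    inc = (p1 - p0) / (1.0 - p0)
                elif keep < 0.0:
                    keep, clamped = 0.0, True
                    inc = p1 / (1.0 - p0)
                rows.append(
                    {
                        "year": year + 1,
                        "sex": sex,
                        "age": age + 1,
                        "keep_prob": float(keep),
                        "inc_target": float(np.clip(inc, 0.0, 1.0)),
                        "clamped": bool(clamped),
                    }
                )
    return pd.DataFrame(
        rows, columns=["year", "sex", "age", "keep_prob", "inc_target", "clamped"]
    )


# ---------------------------------------------------------------------------
# Exacerbation intercept offset
# ---------------------------------------------------------------------------


def calibrate_exacerbation_offset(
    target_vs_rate: float,
    sex: int,
    age: int,
    control_model: ControlModel,
    exac_model: ExacerbationModel,
    severity_model: SeverityModel,
    rng: np.random.Generator,
    n_sim: int = 200_000,
) -> tuple[float, float]:
    """Log-scale intercept correction matching a target very-severe rate.

    Simulates ``n_sim`` zero-offset person-years (fresh random intercepts,
    control proportions, Poisson counts, Dirichlet-multinomial severities
    with no history inflation), then exploits the log-linearity of the
    Poisson mean: offset = log(target) - log(baseline rate).  Returns
    (offset, Monte-Carlo s.e. of the offset).
    """
    if target_vs_rate <= 0:
        raise ValueError("target very-severe rate must be positive")
    b0 = outcomes.draw_control_intercept(control_model.sigma, rng, n_sim)
    ct = outcomes.control_proportions(
        np.full(n_sim, sex), np.full(n_sim, age), b0, control_model
    )
    mean = outcomes.exacerbation_mean(ct, 0.0, exac_model)
    n = outcomes.sample_exacerbations(mean, rng)
    w = outcomes.severity_weights(severity_model, np.zeros(n_sim, dtype=int), rng)
    counts = outcomes.sample_severity_counts(n, w, rng)
    total_vs = int(counts[:, 3].sum())
    if total_vs == 0:
        raise ValueError(
            "no very severe exacerbations simulated at offset 0; increase n_sim"
        )
    baseline = total_vs / n_sim
    mc_se = 1.0 / np.sqrt(total_vs)  # s.e. of log(baseline) for Poisson counts
    return float(np.log(target_vs_rate) - np.log(baseline)), float(mc_se)


# ---------------------------------------------------------------------------
# One-call pipeline
# ---------------------------------------------------------------------------


def calibrate_all(
    inputs: PopulationInputs,
    params: ParameterSet,
    years: list[int],
    min_asthma_age: int = 3,
    stabilisation_year: int = 2025,
    scenario: str | None = None,
) -> CalibrationResult:
    """Run the deterministic calibrations (migration, reassessment with its
    incidence targets, then occurrence offsets) for the given years.

    The cohort accounting is solved first; the per-cell incidence targets it
    emits (where remission alone cannot hold the prevalence curve) feed the
    incidence offset solve.  The exacerbation offset is left at 0 unless
    calibrated separately against an external very-severe rate table.
    """
    mig_years = [y for y in range(min(years), max(years) + 1)]
    migration = calibrate_migration(inputs, years=mig_years, scenario=scenario)
    coeffs = params.occurrence_coeffs

    def prev_fn(year: int, sex: int, age: int) -> float:
        if age < min_asthma_age:
            return 0.0
        return float(
            expit(
                occurrence.prevalence_linear_predictor(
                    year, sex, age, coeffs, stabilisation_year
                )
            )
        )

    def inc_fn(year: int, sex: int, age: int) -> float:
        return float(
            expit(
                occurrence.incidence_linear_predictor(
                    year, sex, age, coeffs, stabilisation_year
                )
            )
        )

    reassess = calibrate_reassessment(
        prev_fn, inc_fn, years, inputs.max_age, min_asthma_age
    )
    inc_targets = {
        (int(r.year), int(r.sex), int(r.age)): float(r.inc_target)
        for r in reassess.itertuples()
    }
    occ = calibrate_occurrence_offsets(
        params, years, inputs.max_age, min_asthma_age, stabilisation_year, inc_targets
    )
    diag_rows = occ.assign(
        abs_error_prev=(occ["achieved_prev"] - occ["target_prev"]).abs(),
        abs_error_inc=(occ["achieved_inc"] - occ["target_inc"]).abs(),
    )[["year", "sex", "age", "abs_error_prev", "abs_error_inc"]]
    return CalibrationResult(
        migration=migration,
        reassessment=reassess[["year", "sex", "age", "keep_prob", "clamped"]],
        occurrence_offsets=occ[["year", "sex", "age", "delta_prev", "delta_inc"]],
        exacerbation_offsets=None,
        diagnostics=diag_rows,
    )
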