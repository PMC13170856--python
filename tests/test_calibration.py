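"""Calibration solves against enumeration and accounting oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from asthmasim import calibration
from asthmasim.params_io import (
    ControlModel,
    ExacerbationModel,
    PopulationInputs,
    SeverityModel,
)


def _stationary_inputs(years, count=1000.0, max_age=3, q=0.0, absorbing_top=True):
    rows = []
    life = []
    births = []
    for year in years:
        for sex in (0, 1):
            for age in range(max_age + 1):
                rows.append(
                    {"year": year, "sex": sex, "age": age, "count": count,
                     "scenario": "medium"}
                )
                life.append(
                    {"year": year, "sex": sex, "age": age,
                     "p_death": 1.0 if (absorbing_top and age == max_age) else q}
                )
        births.append(
            {"year": year, "scenario": "medium", "births": 2 * count,
             "prob_male": 0.5}
        )
    return PopulationInputs(
        population=pd.DataFrame(rows),
        births=pd.DataFrame(births),
        life=pd.DataFrame(life),
    )


class TestMigration:
    def test_stationary_population_zero_flows(self):
        inputs = _stationary_inputs([2019, 2020, 2021])
        table = calibration.calibrate_migration(inputs)
        assert np.allclose(table["net_immigrants"], 0.0)
        assert np.allclose(table["emigration_prob"], 0.0)

    def test_pure_mortality_decline_zero_flows(self):
        """Counts that decay exactly per the life table need no migration."""
        years = [2019, 2020, 2021]
        q = 0.1
        rows, life, births = [], [], []
        count0 = 10_000.0
        max_age = 5
        for i, year in enumerate(years):
            for sex in (0, 1):
                for age in range(max_age + 1):
                    # cohort born in year - age started at count0 and decayed
                    n_decays = min(age, i)
                    rows.append(
                        {"year": year, "sex": sex, "age": age,
                         "count": count0 * (1 - q) ** n_decays,
                         "scenario": "medium"}
                    )
                    life.append(
                        {"year": year, "sex": sex, "age": age,
                         "p_death": 0.0 if age == max_age else q}
                    )
            births.append(
                {"year": year, "scenario": "medium", "births": 2 * count0,
                 "prob_male": 0.5}
            )
        # the absorbing oldest age accumulates; rebuild it consistently
        pop = pd.DataFrame(rows)
        for i, year in enumerate(years[1:], start=1):
            for sex in (0, 1):
                prev_y = pop[(pop.year == year - 1) & (pop.sex == sex)]
                surv_in = float(
                    prev_y.loc[prev_y.age == max_age - 1, "count"].iloc[0]
                ) * (1 - q)
                surv_stay = float(
                    prev_y.loc[prev_y.age == max_age, "count"].iloc[0]
                )
                pop.loc[
                    (pop.year == year) & (pop.sex == sex) & (pop.age == max_age),
                    "count",
                ] = surv_in + surv_stay
        inputs = PopulationInputs(
            population=pop, births=pd.DataFrame(births), life=pd.DataFrame(life)
        )
        table = calibration.calibrate_migration(inputs)
        assert np.allclose(table["net_immigrants"], 0.0, atol=1e-6)
        assert np.allclose(table["emigration_prob"], 0.0, atol=1e-9)

    def test_imposed_jump_recovered_as_immigrants(self):
        inputs = _stationary_inputs([2019, 2020])
        pop = inputs.population.copy()
        mask = (pop.year == 2020) & (pop.sex == 0) & (pop.age == 2)
        pop.loc[mask, "count"] += 1000.0
        inputs = PopulationInputs(
            population=pop, births=inputs.births, life=inputs.life
        )
        table = calibration.calibrate_migration(inputs)
        row = table[(table.year == 2020) & (table.sex == 0) & (table.age == 2)]
        assert float(row["net_immigrants"].iloc[0]) == pytest.approx(1000.0)

    def test_imposed_deficit_becomes_emigration_probability(self):
        inputs = _stationary_inputs([2019, 2020], count=1000.0)
        pop = inputs.population.copy()
        mask = (pop.year == 2020) & (pop.sex == 1) & (pop.age == 2)
        pop.loc[mask, "count"] -= 250.0
        inputs = PopulationInputs(
            population=pop, births=inputs.births, life=inputs.life
        )
        table = calibration.calibrate_migration(inputs)
        # the deficit at (2020, age 2) is emigration of (2019, age 1) residents
        row = table[(table.year == 2019) & (table.sex == 1) & (table.age == 1)]
        assert float(row["emigration_prob"].iloc[0]) == pytest.approx(0.25)

    def test_infeasible_emigration_raises(self):
        # with survivors pooling into the open-ended top age, a target far
        # below the pooled expectation cannot be met by emigrating one cohort
        inputs = _stationary_inputs(
            [2019, 2020], count=1000.0, max_age=3, absorbing_top=False
        )
        pop = inputs.population.copy()
        mask = (pop.year == 2020) & (pop.sex == 1) & (pop.age == 3)
        pop.loc[mask, "count"] = 100.0
        inputs = PopulationInputs(
            population=pop, births=inputs.births, life=inputs.life
        )
        with pytest.raises(ValueError, match="emigration"):
            calibration.calibrate_migration(inputs)


class TestOccurrenceOffset:
    def test_no_effects_closed_form(self):
        """With all effects zero the offset is logit(target) - eta exactly."""
        eta = np.full(8, -1.3)
        w = np.full(8, 1 / 8)
        target = 0.4
        delta = calibration.solve_logit_offset(target, eta, w)
        assert delta == pytest.approx(logit(0.4) - (-1.3), abs=1e-9)

    def test_matches_enumeration_oracle(self, params):
        fha, dose, w = calibration.risk_cell_distribution(1, 2014, params)
        eta = -2.0 + np.zeros_like(w)
        from asthmasim.occurrence import fha_log_or, iae_log_or

        eff = fha_log_or(fha, 5, params.effect_coeffs, "prev") + iae_log_or(
            dose, 5, params.effect_coeffs, "prev"
        )
        target = 0.12
        delta = calibration.solve_logit_offset(target, eta + eff, w)
        # brute-force enumeration over the discrete risk cells
        marginal = sum(
            wi * expit(e + delta) for wi, e in zip(w / w.sum(), eta + eff)
        )
        assert marginal == pytest.approx(target, abs=1e-10)

    def test_marginal_invariant_to_effect_rescaling(self, params):
        """Doubling every effect's odds ratio and re-solving leaves the
        marginal unchanged (the defining property of the offset)."""
        fha, dose, w = calibration.risk_cell_distribution(0, 2012, params)
        from asthmasim.occurrence import fha_log_or, iae_log_or

        target = 0.1
        eta = np.full_like(w, -1.8)
        for scale in (1.0, 2.0):
            eff = scale * (
                fha_log_or(fha, 6, params.effect_coeffs, "inc")
                + iae_log_or(dose, 6, params.effect_coeffs, "inc")
            )
            delta = calibration.solve_logit_offset(target, eta + eff, w)
            marginal = float((w / w.sum()) @ expit(eta + eff + delta))
            assert marginal == pytest.approx(target, abs=1e-10)

    def test_unreachable_target_raises(self):
        with pytest.raises(ValueError):
            calibration.solve_logit_offset(1.0, np.zeros(2), np.full(2, 0.5))

    def test_risk_cell_distribution_sums_to_one(self, params):
        _, _, w = calibration.risk_cell_distribution(0, 2010, params)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)


class TestReassessment:
    @staticmethod
    def _solve(prev_fn, inc_fn, years=(2019, 2020), max_age=12):
        return calibration.calibrate_reassessment(
            prev_fn, inc_fn, list(years), max_age
        )

    def test_constant_prevalence_zero_incidence_keep_one(self):
        table = self._solve(lambda y, s, a: 0.1, lambda y, s, a: 0.0)
        assert np.allclose(table["keep_prob"], 1.0)
        assert not table["clamped"].any()

    def test_halving_prevalence_zero_incidence_keep_half(self):
        def prev(year, sex, age):
            return 0.5 * 0.5 ** (age - 3) if age >= 3 else 0.0

        table = self._solve(prev, lambda y, s, a: 0.0)
        interior = table[table.age > 3]
        assert np.allclose(interior["keep_prob"], 0.5)

    def test_incidence_exactly_replacing_remissions(self):
        """If incidence replaces remissions at constant prevalence, the solved
        keep probability reproduces the accounting identity."""
        p, inc = 0.2, 0.05
        table = self._solve(lambda y, s, a: p, lambda y, s, a: inc)
        # p = p*keep + (1-p)*inc  =>  keep = (p - (1-p)*inc)/p
        expected = (p - (1 - p) * inc) / p
        interior = table[table.age > 3]
        assert np.allclose(interior["keep_prob"], expected)

    def test_growth_beyond_incidence_clamps_and_adjusts_incidence(self):
        def prev(year, sex, age):
            return min(0.05 * max(age - 2, 0), 0.6) if age >= 3 else 0.0

        table = self._solve(prev, lambda y, s, a: 0.0)
        growing = table[(table.age >= 4) & (table.age <= 10)]
        assert growing["clamped"].all()
        assert (growing["keep_prob"] == 1.0).all()
        # inc_target = (p1 - p0)/(1 - p0)
        for r in growing.itertuples():
            p0, p1 = prev(0, 0, r.age - 1), prev(0, 0, r.age)
            assert r.inc_target == pytest.approx((p1 - p0) / (1 - p0))


class TestExacerbationOffset:
    def test_identity_target_gives_near_zero_offset(self, rng):
        cm = ControlModel(sigma=0.5)
        em = ExacerbationModel()
        sm = SeverityModel()
        offset, se = calibration.calibrate_exacerbation_offset(
            0.02, 0, 40, cm, em, sm, np.random.default_rng(1), n_sim=150_000
        )
        baseline = 0.02 / math.exp(offset)
        offset2, se2 = calibration.calibrate_exacerbation_offset(
            baseline, 0, 40, cm, em, sm, np.random.default_rng(2), n_sim=150_000
        )
        assert abs(offset2) < 3 * (se + se2)

    def test_doubling_target_shifts_offset_by_log2(self, rng):
        cm = ControlModel(sigma=0.5)
        em = ExacerbationModel()
        sm = SeverityModel()
        o1, se1 = calibration.calibrate_exacerbation_offset(
            0.02, 1, 30, cm, em, sm, np.random.default_rng(3), n_sim=150_000
        )
        o2, se2 = calibration.calibrate_exacerbation_offset(
            0.04, 1, 30, cm, em, sm, np.random.default_rng(3), n_sim=150_000
        )
        # same rng seed: identical baseline simulation, exact log-2 shift
        assert o2 - o1 == pytest.approx(math.log(2), abs=1e-12)

    def test_invalid_target_rejected(self, rng):
        with pytest.raises(ValueError):
            calibration.calibrate_exacerbation_offset(
                0.0, 0, 40, ControlModel(), ExacerbationModel(), SeverityModel(),
                rng,
            )


class TestIdempotence:
    def test_occurrence_offsets_idempotent(self, fixture_inputs, params,
                                           small_calibration, small_config):
        """Re-solving against the achieved marginals changes nothing."""
        occ = calibration.calibrate_occurrence_offsets(
            params, [2020], fixture_inputs.max_age
        )
        occ2 = calibration.calibrate_occurrence_offsets(
            params, [2020], fixture_inputs.max_age
        )
        assert np.allclose(occ["delta_prev"], occ2["delta_prev"], atol=1e-12)
        assert np.allclose(
            occ["achieved_prev"], occ["target_prev"], atol=1e-9
        )
        assert np.allclose(occ["achieved_inc"], occ["target_inc"], atol=1e-9)

    def test_calibrate_all_diagnostics_tiny(self, small_calibration):
        d = small_calibration.diagnostics
        assert d["abs_error_prev"].max() < 1e-9
        assert d["abs_error_inc"].max() < 1e-9

    def test_result_round_trips_via_csv(self, small_calibration, tmp_path):
        small_calibration.save(tmp_path)
        loaded = calibration.CalibrationResult.load(tmp_path)
        pd.testing.assert_frame_equal(
            loaded.occurrence_offsets,
            small_calibration.occurrence_offsets.reset_index(drop=True),
            check_dtype=False,
        )
        pd.testing.assert_frame_equal(
            loaded.migration,
            small_calibration.migration.reset_index(drop=True),
            check_dtype=False,
        )
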