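"""Full simulation loop: determinism, conservation, invariants, CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from asthmasim import (
    PopulationInputs,
    SimulationConfig,
    aggregate_and_write,
    run_simulation,
)
from asthmasim.cli import main as cli_main
from asthmasim.engine import STRATUM_MEASURES


@pytest.fixture(scope="module")
def run_outcomes(small_config, fixture_inputs, params, small_calibration):
    return run_simulation(small_config, fixture_inputs, params, small_calibration)


class TestDeterminism:
    def test_fixed_seed_reruns_are_identical(
        self, small_config, fixture_inputs, params, small_calibration, tmp_path
    ):
        out1 = run_simulation(small_config, fixture_inputs, params, small_calibration)
        out2 = run_simulation(small_config, fixture_inputs, params, small_calibration)
        pd.testing.assert_frame_equal(out1.strata, out2.strata)
        p1 = aggregate_and_write(out1, tmp_path / "a", small_config, params)
        p2 = aggregate_and_write(out2, tmp_path / "b", small_config, params)
        assert p1["outcomes"].read_bytes() == p2["outcomes"].read_bytes()
        assert p1["summary"].read_bytes() == p2["summary"].read_bytes()

    def test_different_seed_differs(
        self, small_config, fixture_inputs, params, small_calibration, run_outcomes
    ):
        cfg = small_config.model_copy(update={"rng_seed": 999})
        other = run_simulation(cfg, fixture_inputs, params, small_calibration)
        assert not other.strata.equals(run_outcomes.strata)


class TestConservation:
    def test_identity_exact_every_cycle_and_sex(self, run_outcomes):
        errors = run_outcomes.conservation_errors()
        assert not errors.empty
        assert (errors["error"] == 0).all()

    def test_all_counts_nonnegative(self, run_outcomes):
        assert (run_outcomes.strata[STRATUM_MEASURES] >= -1e-12).all().all()

    def test_labelled_never_exceeds_population(self, run_outcomes):
        s = run_outcomes.strata
        assert (s["asthma_count"] <= s["population"]).all()


class TestInvariants:
    def test_no_label_under_minimum_age(self, run_outcomes, small_config):
        young = run_outcomes.strata.query("age < @small_config.min_asthma_age")
        assert young["asthma_count"].sum() == 0
        assert young["incident"].sum() == 0

    def test_control_time_sums_to_labelled_count(self, run_outcomes):
        s = run_outcomes.strata
        ct_total = s["ct_uc"] + s["ct_pc"] + s["ct_wc"]
        assert np.allclose(ct_total, s["asthma_count"])

    def test_exacerbations_only_among_labelled(self, run_outcomes):
        s = run_outcomes.strata
        exac = s[["exac_mild", "exac_moderate", "exac_severe", "exac_very_severe"]]
        assert (exac.sum(axis=1)[s["asthma_count"] == 0] == 0).all()

    def test_per_patient_control_cost_stable_over_years(self, run_outcomes):
        """Constant tariffs must give a stable annual per-patient control
        cost trajectory."""
        t = run_outcomes.summary()
        by_year = t.groupby("year")["cost_control_per_patient"].mean()
        assert by_year.std() / by_year.mean() < 0.05

    def test_absorbing_life_table_empties_population(self, fixture_inputs, params):
        life = fixture_inputs.life.copy()
        life["p_death"] = 1.0
        inputs = PopulationInputs(
            population=fixture_inputs.population,
            births=fixture_inputs.births,
            life=life,
        )
        cfg = SimulationConfig(
            base_year=2019, horizon_end=2021, population_scale=1e-4, rng_seed=0
        )
        out = run_simulation(cfg, inputs, params)
        t = out.totals_by_sex().groupby("year").sum(numeric_only=True)
        assert t.loc[2019, "deaths"] == t.loc[2019, "population"]
        # only newborn cohorts remain in later years
        assert t.loc[2020, "population"] == t.loc[2020, "births"]
        assert (out.conservation_errors()["error"] == 0).all()

    def test_fast_forward_records_start_at_base_year(
        self, fixture_inputs, params
    ):
        cfg = SimulationConfig(
            base_year=2022, horizon_end=2023, population_scale=1e-4, rng_seed=3
        )
        out = run_simulation(cfg, fixture_inputs, params)
        assert sorted(out.strata["year"].unique()) == [2022, 2023]

    def test_coverage_gap_aborts_before_simulating(self, fixture_inputs, params):
        cfg = SimulationConfig(base_year=2019, horizon_end=2040)
        with pytest.raises(ValueError, match="cover"):
            run_simulation(cfg, fixture_inputs, params)


class TestRngStreamIsolation:
    def test_outcome_module_changes_do_not_move_demography(
        self, small_config, fixture_inputs, params, small_calibration, run_outcomes
    ):
        """Doubling the control-model sigma must leave the demographic
        trajectory untouched (separate RNG substreams per module)."""
        params2 = params.model_copy(deep=True)
        params2.control_model.sigma = params.control_model.sigma * 2
        out2 = run_simulation(small_config, fixture_inputs, params2, small_calibration)
        demo_cols = ["population", "births", "immigrants", "deaths", "emigrants"]
        pd.testing.assert_frame_equal(
            out2.strata[["year", "sex", "age"] + demo_cols],
            run_outcomes.strata[["year", "sex", "age"] + demo_cols],
        )


class TestAggregation:
    def test_stratum_qalys_sum_to_grand_total(self, run_outcomes):
        total = run_outcomes.strata["qalys"].sum()
        by_sex = run_outcomes.totals_by_sex()["qalys"].sum()
        assert by_sex == pytest.approx(total)

    def test_written_files_and_metadata(
        self, run_outcomes, small_config, params, tmp_path
    ):
        paths = aggregate_and_write(run_outcomes, tmp_path, small_config, params)
        assert paths["outcomes"].exists()
        meta = json.loads(paths["metadata"].read_text())
        assert meta["config"]["rng_seed"] == small_config.rng_seed
        assert meta["parameter_version"] == params.version

    def test_empty_outcomes_write_header_only(self, tmp_path):
        from asthmasim.engine import AnnualOutcomes

        empty = AnnualOutcomes(
            strata=pd.DataFrame(columns=["year", "sex", "age"] + STRATUM_MEASURES)
        )
        paths = aggregate_and_write(empty, tmp_path)
        lines = paths["outcomes"].read_text().strip().splitlines()
        assert len(lines) == 1


class TestCli:
    def test_end_to_end_pipeline(self, tmp_path):
        runner = CliRunner()
        fx = tmp_path / "fx"
        steps = [
            ["fixtures", "--out", str(fx), "--max-age", "60",
             "--year-start", "2018", "--year-end", "2022"],
            ["calibrate", "--inputs", str(fx), "--params",
             str(fx / "parameters.json"), "--base-year", "2019",
             "--horizon", "2021", "--out", str(tmp_path / "cal")],
            ["validate", "--inputs", str(fx), "--params",
             str(fx / "parameters.json"), "--base-year", "2019",
             "--horizon", "2021"],
            ["simulate", "--inputs", str(fx), "--params",
             str(fx / "parameters.json"), "--calibration",
             str(tmp_path / "cal"), "--seed", "7", "--scale", "1e-4",
             "--base-year", "2019", "--horizon", "2021",
             "--out", str(tmp_path / "run")],
        ]
        for argv in steps:
            result = runner.invoke(cli_main, argv, catch_exceptions=False)
            assert result.exit_code == 0, result.output
        assert (tmp_path / "run" / "outcomes.csv").exists()

    def test_simulate_same_seed_identical_outputs(self, tmp_path):
        runner = CliRunner()
        fx = tmp_path / "fx"
        runner.invoke(
            cli_main,
            ["fixtures", "--out", str(fx), "--max-age", "50",
             "--year-start", "2019", "--year-end", "2021"],
            catch_exceptions=False,
        )
        outs = []
        for name in ("r1", "r2"):
            runner.invoke(
                cli_main,
                ["simulate", "--inputs", str(fx), "--params",
                 str(fx / "parameters.json"), "--seed", "7", "--scale", "1e-4",
                 "--base-year", "2019", "--horizon", "2021",
                 "--out", str(tmp_path / name)],
                catch_exceptions=False,
            )
            outs.append((tmp_path / name / "outcomes.csv").read_bytes())
        assert outs[0] == outs[1]

    def test_validate_reports_gaps_with_nonzero_exit(self, tmp_path):
        runner = CliRunner()
        fx = tmp_path / "fx"
        runner.invoke(
            cli_main,
            ["fixtures", "--out", str(fx), "--max-age", "50",
             "--year-start", "2019", "--year-end", "2021"],
            catch_exceptions=False,
        )
        result = runner.invoke(
            cli_main,
            ["validate", "--inputs", str(fx), "--params",
             str(fx / "parameters.json"), "--base-year", "2019",
             "--horizon", "2030"],
        )
        assert result.exit_code != 0
        assert "life" in result.output or "births" in result.output
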