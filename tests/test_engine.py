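"""Pipeline orchestration: determinism, Monte Carlo contract, sensitivity, CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from pmslt.cli import main as cli_main
from pmslt.engine import (
    McSettings,
    monte_carlo,
    run_all,
    run_scenario,
    sensitivity_suite,
)
from pmslt.exposure import default_scenarios, null_scenario
from pmslt.lifetable_econ import EconSettings

DEGENERATE = dict(rr20_log_sd=0.0, slope_rel_sd=0.0, intake_se_scale=0.0,
                  cost_cv=0.0, cf_log_sd=0.0)


class TestRunScenario:
    def test_rerun_is_bit_identical(self, model_inputs, scenario_map):
        a = run_scenario(model_inputs, scenario_map["S3"])
        b = run_scenario(model_inputs, scenario_map["S3"])
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_null_scenario_all_outcomes_zero(self, model_inputs):
        out = run_scenario(model_inputs, null_scenario())
        assert np.abs(out.to_numpy()).max() == 0.0

    def test_larger_reduction_dominates_componentwise(self, model_inputs, scenario_map):
        s1 = run_scenario(model_inputs, scenario_map["S1"])
        s2 = run_scenario(model_inputs, scenario_map["S2"])
        assert (s1.to_numpy() >= s2.to_numpy()).all()
        assert s1[("qalys", "all", "all")] > s2[("qalys", "all", "all")]

    def test_run_all_covers_every_scenario(self, model_inputs):
        frame = run_all(model_inputs, default_scenarios()[:2])
        assert set(frame.scenario) == {"S1", "S2"}
        assert {"prevented_cases", "qalys", "savings_cad"} <= set(frame.outcome)


class TestMonteCarlo:
    def test_degenerate_distributions_collapse_to_point(self, model_inputs, scenario_map):
        mc = McSettings(n_iterations=3, seed=5, **DEGENERATE)
        out = monte_carlo(model_inputs, scenario_map["S3"], mc)
        np.testing.assert_array_equal(out.lo95.to_numpy(), out.hi95.to_numpy())
        np.testing.assert_allclose(out.lo95.to_numpy(), out.point.to_numpy(), rtol=1e-12)

    def test_same_seed_reproducible(self, model_inputs, scenario_map):
        mc = McSettings(n_iterations=8, seed=11)
        a = monte_carlo(model_inputs, scenario_map["S4"], mc)
        b = monte_carlo(model_inputs, scenario_map["S4"], mc)
        pd.testing.assert_frame_equal(a, b)

    def test_intervals_ordered_and_finite(self, model_inputs, scenario_map):
        mc = McSettings(n_iterations=16, seed=2)
        out = monte_carlo(model_inputs, scenario_map["S3"], mc)
        assert (out.lo95 <= out.hi95).all()
        assert np.isfinite(out.to_numpy()).all()

    def test_too_few_iterations_rejected(self, model_inputs, scenario_map):
        with pytest.raises(ValueError, match="n >= 2"):
            monte_carlo(model_inputs, scenario_map["S3"], McSettings(n_iterations=1))


@pytest.fixture(scope="module")
def table(model_inputs, scenario_map):
    return sensitivity_suite(model_inputs, scenario_map["S6"])


class TestSensitivity:
    def _totals(self, table, outcome):
        sub = table[(table.outcome == outcome) & (table.disease == "all") & (table.sex == "all")]
        return sub.pivot(index="discount_rate", columns="horizon", values="value")

    @pytest.mark.parametrize("outcome", ["qalys", "savings_cad"])
    def test_discount_ordering(self, table, outcome):
        t = self._totals(table, outcome)["lifetime"]
        assert t[0.0] > t[0.015] > t[0.03] > 0

    @pytest.mark.parametrize("outcome", ["prevented_cases", "qalys", "savings_cad"])
    def test_horizon_ordering(self, table, outcome):
        t = self._totals(table, outcome)
        for rate in (0.0, 0.015, 0.03):
            assert 0 < t.loc[rate, 10] < t.loc[rate, 50] < t.loc[rate, "lifetime"]

    def test_shares_are_cumulative_fractions(self, table):
        sub = table[(table.outcome == "savings_cad") & (table.disease == "all") & (table.sex == "all")]
        shares = sub.pivot(index="discount_rate", columns="horizon", values="share_of_lifetime")
        for rate in (0.0, 0.015, 0.03):
            assert 0 < shares.loc[rate, 10] < shares.loc[rate, 50] < 1.0
            assert shares.loc[rate, "lifetime"] == pytest.approx(1.0)

    def test_undiscounted_lifetime_equals_annual_sum(self, model_inputs, scenario_map):
        """At r = 0 the lifetime total is the plain sum of annual streams,
        so it must match a horizon long enough to cover every cohort."""
        free = run_scenario(model_inputs, scenario_map["S6"], EconSettings(0.0, None))
        capped = run_scenario(model_inputs, scenario_map["S6"], EconSettings(0.0, 81))
        np.testing.assert_allclose(free.to_numpy(), capped.to_numpy(), rtol=1e-9)


class TestCli:
    def test_generate_run_mc_roundtrip(self, tmp_path):
        runner = CliRunner()
        indir = tmp_path / "inputs"
        res = runner.invoke(cli_main, ["generate", "--seed", "2", "--total-size", "1000000",
                                       "--outdir", str(indir)])
        assert res.exit_code == 0, res.output
        assert (indir / "population.csv").exists()

        outdir = tmp_path / "run"
        res = runner.invoke(cli_main, ["run", "--inputs", str(indir), "--scenario", "S3",
                                       "--outdir", str(outdir)])
        assert res.exit_code == 0, res.output
        frame = pd.read_csv(outdir / "results.csv")
        total = frame[(frame.outcome == "prevented_cases") & (frame.disease == "all")
                      & (frame.sex == "all")].value.iloc[0]
        assert total > 0

        mcdir = tmp_path / "mc"
        res = runner.invoke(cli_main, ["mc", "--inputs", str(indir), "--scenario", "S4",
                                       "--iterations", "4", "--outdir", str(mcdir)])
        assert res.exit_code == 0, res.output
        assert (mcdir / "results.csv").exists()
        assert (mcdir / "metadata.json").exists()

    def test_unknown_scenario_fails_cleanly(self, tmp_path):
        runner = CliRunner()
        indir = tmp_path / "inputs"
        runner.invoke(cli_main, ["generate", "--seed", "2", "--total-size", "1000000",
                                 "--outdir", str(indir)])
        res = runner.invoke(cli_main, ["run", "--inputs", str(indir), "--scenario", "S99",
                                       "--outdir", str(tmp_path / "x")])
        assert res.exit_code != 0
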