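"""Scenario arithmetic, dose-response pathway and potential impact fractions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pmslt.exposure import (
    EffectModel,
    Scenario,
    apply_scenario,
    default_scenarios,
    percent_reduction,
    pif_distributional,
    pif_mean_shift,
    pif_table,
    required_reduction,
    rr_multiplier,
    sbp_shift,
    sodium_delta_by_age,
    sodium_to_salt,
)
from pmslt.grids import DRI_LABELS, SEXES


class TestScenarioArithmetic:
    @pytest.mark.parametrize(
        "baseline,recommendation,expected",
        [(2758.0, 1500.0, 1258.0), (2758.0, 2000.0, 758.0), (1400.0, 1500.0, 0.0)],
    )
    def test_required_reduction(self, baseline, recommendation, expected):
        assert required_reduction(baseline, recommendation) == expected

    @pytest.mark.parametrize(
        "delta,expected",
        [(1258.0, 3.14), (459.0, 1.15), (212.0, 0.53), (128.0, 0.32), (174.0, 0.44), (0.0, 0.0)],
    )
    def test_salt_equivalent(self, delta, expected):
        assert sodium_to_salt(delta) == expected

    def test_percent_reduction(self):
        assert percent_reduction(459.0, 2758.0) == pytest.approx(16.64, abs=0.005)
        assert round(percent_reduction(459.0, 2758.0)) == 17
        assert percent_reduction(0.0, 2758.0) == 0.0
        assert percent_reduction(1379.0, 2758.0) == pytest.approx(50.0)


class TestApplyScenario:
    def _means(self, value):
        return {(sex, g): value for sex in SEXES for g in DRI_LABELS}

    def test_proportional_reduction(self):
        sc = Scenario("X", "proportional", 0.047)
        out = apply_scenario(self._means(3000.0), sc)
        assert out[("male", "19-30")] == pytest.approx(2859.0)

    def test_zero_delta_is_identity(self):
        sc = Scenario("X", "absolute_delta", 0.0)
        means = self._means(2758.0)
        assert apply_scenario(means, sc) == means

    def test_target_never_increases_intake(self):
        sc = Scenario("X", "target_level", 2300.0)
        out = apply_scenario(self._means(2100.0), sc)
        assert out[("male", "19-30")] == 2100.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            Scenario("X", "magic", 1.0)

    def test_children_get_no_intervention(self):
        sc = Scenario("X", "absolute_delta", 500.0)
        delta = sodium_delta_by_age(self._means(2758.0), sc, "male")
        assert delta[:19].max() == 0.0
        assert delta[19:].min() == 500.0


class TestDoseResponse:
    def test_sbp_shift_units(self):
        assert sbp_shift(1000.0, 2.0) == pytest.approx(-2.0)
        assert sbp_shift(0.0, 2.0) == 0.0
        assert sbp_shift(500.0, 1.2) == pytest.approx(-0.6)

    @pytest.mark.parametrize(
        "dsbp,rr20,expected",
        [(-20.0, 2.0, 0.5), (0.0, 1.7, 1.0), (-10.0, 2.0, 2 ** -0.5)],
    )
    def test_rr_multiplier(self, dsbp, rr20, expected):
        assert rr_multiplier(dsbp, rr20) == pytest.approx(expected, rel=1e-12)

    def test_rr_below_one_rejected(self):
        with pytest.raises(ValueError, match=">= 1"):
            rr_multiplier(-10.0, 0.9)

    def test_pif_zero_when_no_risk_gradient(self):
        assert pif_mean_shift(-15.0, 1.0) == 0.0

    def test_pif_half_for_full_rr_unit(self):
        assert pif_mean_shift(-20.0, 2.0) == pytest.approx(0.5)

    def test_distributional_equals_mean_shift_for_uniform_shift(self):
        """Under log-linear risk a uniform shift of every support point gives
        exactly the mean-shift PIF."""
        support = np.array([2000.0, 2800.0, 3600.0])
        weights = np.array([0.3, 0.5, 0.2])
        delta, slope, rr20 = 459.0, 2.0, 1.8
        p_dist = pif_distributional(support, weights, support - delta, rr20, slope)
        p_mean = pif_mean_shift(sbp_shift(delta, slope), rr20)
        assert p_dist == pytest.approx(p_mean, abs=1e-12)

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            pif_distributional([1.0], [0.5], [1.0], 2.0, 2.0)

    @given(st.floats(min_value=0.0, max_value=2000.0), st.floats(min_value=0.0, max_value=1000.0))
    def test_pif_monotone_in_reduction(self, delta, extra):
        """A larger sodium reduction never lowers the PIF."""
        slope, rr20 = 2.0, 1.8
        p1 = pif_mean_shift(sbp_shift(delta, slope), rr20)
        p2 = pif_mean_shift(sbp_shift(delta + extra, slope), rr20)
        assert p2 >= p1


class TestShippedScenarios:
    def test_ten_scenarios_with_expected_kinds(self):
        scenarios = {s.id: s for s in default_scenarios()}
        assert len(scenarios) == 10
        assert scenarios["S1"].kind == "target_level"
        assert scenarios["S4"].kind == "proportional"
        assert scenarios["S10"].kind == "absolute_delta"

    def test_population_mean_pif_follows_delta_ordering(self, synthetic_inputs):
        """Scenario ordering by overall sodium delta induces the same
        ordering of the population-mean PIF."""
        means = synthetic_inputs.sodium.mean
        weights = synthetic_inputs.sodium.weights
        effect = EffectModel()
        order = ["S7", "S4", "S8", "S5", "S9", "S6", "S10", "S3", "S2", "S1"]
        scenarios = {s.id: s for s in default_scenarios()}
        deltas, pifs = [], []
        for sid in order:
            sc = scenarios[sid]
            cf = apply_scenario(means, sc)
            deltas.append(sum(weights[k] * (means[k] - cf[k]) for k in means))
            table = pif_table(means, sc, effect)
            pifs.append(np.mean([table[d][19:, :].mean() for d in table]))
        assert all(d2 > d1 for d1, d2 in zip(deltas, deltas[1:]))
        assert all(p2 > p1 for p1, p2 in zip(pifs, pifs[1:]))

    def test_null_scenario_gives_zero_pif_exactly(self, synthetic_inputs):
        from pmslt.exposure import null_scenario

        table = pif_table(synthetic_inputs.sodium.mean, null_scenario(), EffectModel())
        for d, pif in table.items():
            assert np.abs(pif).max() == 0.0
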