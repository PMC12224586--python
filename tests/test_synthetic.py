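"""Synthetic input generator: determinism, conservation, internal consistency."""

import numpy as np
import pytest

from pmslt.disease_model import rate_to_prob
from pmslt.grids import AGES, MAX_AGE, SEXES, AgeSexGrid
from pmslt.synthetic import (
    DEFAULT_TARGET_SODIUM,
    TrueEpiParams,
    adult_dri_weights,
    generate_costs_utilities,
    generate_disease_epi,
    generate_inputs,
    generate_population,
    generate_sbp,
    generate_sodium_intakes,
    gompertz_makeham,
    read_inputs,
    write_inputs,
)


class TestPopulation:
    def test_total_conserved_exactly(self):
        pop = generate_population(seed=1, total_size=1_000_000)
        assert pop.population.total() == 1_000_000.0

    def test_same_seed_identical(self):
        a = generate_population(seed=7)
        b = generate_population(seed=7)
        np.testing.assert_array_equal(a.population.values, b.population.values)
        np.testing.assert_array_equal(a.all_cause_mortality.values, b.all_cause_mortality.values)

    def test_different_seed_differs(self):
        a = generate_population(seed=7)
        b = generate_population(seed=8)
        assert not np.array_equal(a.population.values, b.population.values)

    def test_degenerate_hazard_is_flat(self):
        m = gompertz_makeham(AGES, alpha=0.001, beta=0.0, gamma=0.5)
        np.testing.assert_array_equal(m, 0.001)

    def test_gompertz_doubling_ratio(self):
        m = gompertz_makeham(AGES, alpha=0.0, beta=1e-5, gamma=0.09)
        assert m[80] / m[40] == pytest.approx(np.exp(0.09 * 40), rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_population(seed=1, total_size=0)
        with pytest.raises(ValueError):
            gompertz_makeham(AGES, alpha=-1.0, beta=1e-5, gamma=0.1)


class TestDiseaseEpi:
    def _params(self, incidence, case_fatality):
        i = AgeSexGrid.from_columns(male=incidence, female=incidence)
        f = AgeSexGrid.from_columns(male=case_fatality, female=case_fatality)
        return TrueEpiParams(i, f)

    def test_zero_case_fatality_means_no_cause_deaths(self):
        pop = generate_population(seed=1, total_size=1e6)
        params = self._params(np.full(101, 0.01), np.zeros(101))
        epi = generate_disease_epi(1, params, pop)
        assert epi.cause_mortality.values.max() == 0.0

    def test_zero_incidence_means_no_prevalence(self):
        pop = generate_population(seed=1, total_size=1e6)
        params = self._params(np.zeros(101), np.full(101, 0.2))
        epi = generate_disease_epi(1, params, pop)
        assert epi.prevalence.values.max() == 0.0

    def test_forward_process_matches_hand_recursion(self):
        """Constant rates: generated prevalence equals an independently
        hand-run forward recursion and approaches its steady state."""
        pop = generate_population(seed=1, total_size=1e6)
        i, f = 0.01, 0.2
        params = self._params(np.full(101, i), np.full(101, f))
        epi = generate_disease_epi(1, params, pop)

        qi, qf = 1 - np.exp(-i), 1 - np.exp(-f)
        S, C = 1.0, 0.0
        for _ in range(MAX_AGE):
            new, die = S * qi, C * qf
            S, C = S - new, C + new - die
        assert epi.prevalence[100, "male"] == pytest.approx(C / (S + C), abs=1e-12)
        # long-run steady state of the same recursion
        for _ in range(200):
            new, die = S * qi, C * qf
            S, C = S - new, C + new - die
        steady = C / (S + C)
        assert epi.prevalence[100, "male"] == pytest.approx(steady, rel=0.05)

    def test_generated_triple_consistent_with_recursion(self, synthetic_inputs):
        """Forward-generated (incidence, prevalence, cause mortality) satisfy
        the three-state recursion with the true case fatality to 1e-9."""
        for disease, data in synthetic_inputs.epi.items():
            params = synthetic_inputs.epi_params[disease]
            for sex in SEXES:
                qi = rate_to_prob(params.incidence.sex(sex))
                qf = rate_to_prob(params.case_fatality.sex(sex))
                S, C = np.zeros(101), np.zeros(101)
                S[0] = 1.0
                for a in range(MAX_AGE):
                    new, die = S[a] * qi[a], C[a] * qf[a]
                    S[a + 1], C[a + 1] = S[a] - new, C[a] + new - die
                alive = S + C
                np.testing.assert_allclose(
                    data.prevalence.sex(sex), C / alive, atol=1e-9
                )
                np.testing.assert_allclose(
                    data.cause_mortality.sex(sex), C * qf / alive, atol=1e-9
                )

    def test_remission_must_be_zero(self):
        g = AgeSexGrid.full(0.01)
        with pytest.raises(ValueError, match="remission"):
            TrueEpiParams(g, g, remission=0.1)


class TestSodium:
    def test_default_weighted_mean_hits_target(self, synthetic_inputs):
        assert synthetic_inputs.sodium.population_weighted_mean == pytest.approx(
            DEFAULT_TARGET_SODIUM, abs=1.0
        )

    def test_weighted_mean_is_weighted_sum(self):
        means = {("male", "19-30"): 2000.0, ("male", "31-50"): 3000.0,
                 ("male", "51-70"): 2000.0, ("male", "71+"): 3000.0,
                 ("female", "19-30"): 2000.0, ("female", "31-50"): 3000.0,
                 ("female", "51-70"): 2000.0, ("female", "71+"): 3000.0}
        weights = {k: 0.125 for k in means}
        out = generate_sodium_intakes(1, means, weights, target_mean=None)
        assert out.population_weighted_mean == pytest.approx(2500.0)

    def test_bad_weights_rejected(self):
        means = {("male", "19-30"): 2000.0}
        with pytest.raises(ValueError, match="sum to 1"):
            generate_sodium_intakes(1, means, {("male", "19-30"): 0.5})

    def test_adult_weights_sum_to_one(self, synthetic_inputs):
        w = adult_dri_weights(synthetic_inputs.population)
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)


class TestSBP:
    def test_eighty_plus_carries_sixty_to_seventy_nine(self):
        sbp = generate_sbp(1)
        for sex in SEXES:
            by_band = {(lo, hi): v for lo, hi, v in sbp.bands[sex]}
            assert by_band[(80, MAX_AGE)] == by_band[(60, 79)]

    def test_flat_bands_stay_flat(self):
        bands = {s: [(lo, hi, 120.0) for lo, hi in
                     [(6, 11), (12, 19), (20, 39), (40, 59), (60, 79)]] for s in SEXES}
        sbp = generate_sbp(1, bands)
        for sex in SEXES:
            assert {v for _, _, v in sbp.bands[sex]} == {120.0}

    def test_missing_band_rejected(self):
        bands = {s: [(6, 11, 100.0)] for s in SEXES}
        with pytest.raises(ValueError, match="missing SBP band"):
            generate_sbp(1, bands)


class TestCostsUtilities:
    def test_flat_per_case_cost_without_jitter(self):
        prevalent = {d: np.ones((6, 2)) for d in ("ihd", "stroke")}
        out = generate_costs_utilities(
            1,
            {
                "prevalent_by_band": prevalent,
                "per_case_cost": {"ihd": 1000.0, "stroke": 1000.0},
                "cost_jitter_sd": 0.0,
            },
        )
        for d in ("ihd", "stroke"):
            np.testing.assert_array_equal(out.attributable[d], 1000.0)

    def test_utility_bounds_enforced(self):
        prevalent = {d: np.ones((6, 2)) for d in ("ihd", "stroke")}
        with pytest.raises(ValueError, match="utility"):
            generate_costs_utilities(
                1, {"prevalent_by_band": prevalent, "background_utility": [1.2] * 10}
            )


def test_full_bundle_deterministic_and_roundtrips(tmp_path):
    a = generate_inputs(seed=3, total_size=1e6)
    b = generate_inputs(seed=3, total_size=1e6)
    np.testing.assert_array_equal(a.population.population.values, b.population.population.values)
    assert a.sodium.mean == b.sodium.mean

    write_inputs(a, tmp_path)
    c = read_inputs(tmp_path)
    np.testing.assert_allclose(c.population.population.values, a.population.population.values)
    np.testing.assert_allclose(
        c.epi["ihd"].prevalence.values, a.epi["ihd"].prevalence.values, atol=1e-12
    )
    for key, v in a.sodium.mean.items():
        assert c.sodium.mean[key] == pytest.approx(v)
    np.testing.assert_allclose(
        c.costs.unattributable_total, a.costs.unattributable_total
    )
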