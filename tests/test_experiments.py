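"""Optimal social action, reversal scans, mutation sweeps, mutation-fixation chain."""

import numpy as np
import pytest

import demosoc as ds
from conftest import make_model1, make_model2


class TestOptimalAction:
    def test_altruism_printed_parameters(self):
        """beta = 2d makes |beta - 2d| vanish, so nu* = kappa1 = 0.75 exactly."""
        res = ds.optimal_social_action(
            "birth_altruism", {"beta": 1, "d": 0.5, "kappa1": 0.75, "kappa2": 0.01}
        )
        assert res.nu_star_closed == 0.75
        assert res.nu_star_numeric == pytest.approx(0.75, abs=1e-6)
        assert not res.boundary_optimum

    def test_spite_printed_parameters(self):
        res = ds.optimal_social_action(
            "birth_spite", {"beta": 8, "d": 1, "a": 0.05, "kappa1": 0.05, "kappa2": 0.2}
        )
        # closed form: (a + theta)(beta - 2d - kappa1 theta)/(beta theta), theta = sqrt(5)
        theta = np.sqrt(5)
        expected = (0.05 + theta) * (8 - 2 - 0.05 * theta) / (8 * theta)
        assert res.nu_star_closed == pytest.approx(expected, abs=1e-12)
        assert round(res.nu_star_closed, 2) == 0.75
        assert res.nu_star_numeric == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("kappa1", [0.4, 0.75, 1.1])
    def test_altruism_balanced_rates_give_kappa1(self, kappa1):
        res = ds.optimal_social_action(
            "birth_altruism", {"beta": 2.0, "d": 1.0, "kappa1": kappa1, "kappa2": 0.05}
        )
        assert res.nu_star_closed == pytest.approx(kappa1, abs=1e-12)

    @pytest.mark.parametrize(
        "params",
        [
            {"beta": 1.2, "d": 0.5, "kappa1": 0.9, "kappa2": 0.02},
            {"beta": 3.0, "d": 1.3, "kappa1": 0.6, "kappa2": 0.1},
            {"beta": 1.0, "d": 0.45, "kappa1": 1.4, "kappa2": 0.008},
        ],
    )
    def test_altruism_numeric_matches_closed_form(self, params):
        """Interior optima with beta >= 2d: numeric minimizer agrees to 1e-6."""
        res = ds.optimal_social_action("birth_altruism", params)
        assert res.nu_star_closed is not None and not res.boundary_optimum
        assert res.nu_star_numeric == pytest.approx(res.nu_star_closed, abs=1e-6)
        # optimality: the objective does not improve at perturbed nu
        for dnu in (-0.05, 0.05):
            other = ds.make_model(
                "birth_altruism", dict(params, nu=res.nu_star_numeric + dnu), omega=1.0
            )
            n1 = ds.quasi_equilibrium_density(other, 1.0)
            assert ds.turnover(other, 1.0, n1) / n1 >= res.objective - 1e-12

    @pytest.mark.parametrize(
        "params",
        [
            {"beta": 8, "d": 1, "a": 0.05, "kappa1": 0.05, "kappa2": 0.2},
            {"beta": 6, "d": 0.8, "a": 0.2, "kappa1": 0.1, "kappa2": 0.3},
        ],
    )
    def test_spite_numeric_matches_closed_form(self, params):
        res = ds.optimal_social_action("birth_spite", params)
        assert res.nu_star_closed is not None and not res.boundary_optimum
        assert res.nu_star_numeric == pytest.approx(res.nu_star_closed, abs=1e-6)

    def test_altruism_absolute_value_mismatch_below_balanced_rates(self):
        """With beta < 2d the |beta - 2d| closed form and the true interior
        optimum part ways: the minimizer sits at kappa1 - (beta - 2d)/theta,
        i.e. *above* kappa1.  The numeric search is authoritative there."""
        params = {"beta": 0.8, "d": 0.45, "kappa1": 1.4, "kappa2": 0.008}
        res = ds.optimal_social_action("birth_altruism", params)
        theta = np.sqrt(0.45 / 0.008)
        signed = 1.4 - (0.8 - 0.9) / theta
        assert res.nu_star_numeric == pytest.approx(signed, abs=1e-6)
        assert res.nu_star_closed == pytest.approx(1.4 - abs(0.8 - 0.9) / theta, abs=1e-12)
        assert res.nu_star_numeric != pytest.approx(res.nu_star_closed, abs=1e-3)


class TestReversal:
    def test_model1_never_reverses(self):
        model = make_model1(100, 0.02, epsilon=0.003)
        table = ds.reversal_scan(model, [50, 100, 400, 2000], [0.003])
        assert not table["favoured"].any()
        assert not table["reversal"].any()

    def test_model1_cost_free_mass_exactly_half(self):
        model = make_model1(100, 0.02, epsilon=0.0)
        table = ds.reversal_scan(model, [50, 200, 1000], [0.0])
        assert np.allclose(table["mass_above_half"], 0.5, atol=1e-9)

    def test_model2_reversal_at_small_habitat(self):
        """Model 2 flips to favoured as the habitat shrinks (stochasticity grows)."""
        model = make_model2(100, 0.02, epsilon=0.003)
        table = ds.reversal_scan(model, [100, 2000], [0.003])
        small = table[table.omega == 100].iloc[0]
        large = table[table.omega == 2000].iloc[0]
        assert small["favoured"] and small["reversal"]
        assert not large["favoured"]

    def test_matched_pair_identical_drift_opposite_verdicts(self):
        """The central contrast: same alpha(p), different stochastic outcomes."""
        m1 = make_model1(100, 0.02, epsilon=0.003)
        m2 = make_model2(100, 0.02, epsilon=0.003)
        for p in np.linspace(0.01, 0.99, 21):
            a1, _ = ds.diffusion_coefficients(m1, float(p))
            a2, _ = ds.diffusion_coefficients(m2, float(p))
            assert abs(a1 - a2) < 1e-10
        rep1 = ds.favourability(ds.stationary_density(m1))
        rep2 = ds.favourability(ds.stationary_density(m2))
        assert not rep1.favoured
        assert rep2.favoured and rep2.reversal

    def test_reversal_boundary_bisection(self):
        model = make_model2(100, 0.02, epsilon=0.003)
        omega_star = ds.find_reversal_omega(model, (100, 2000))
        assert 100 < omega_star < 2000
        below = ds.stationary_density(model.with_(omega=omega_star * 0.8))
        above = ds.stationary_density(model.with_(omega=omega_star * 1.25))
        assert below.mass_above_half > 0.5 > above.mass_above_half

    def test_non_integrable_cells_reported_not_fatal(self):
        model = make_model1(100, 0.02, epsilon=0.003).with_(mu=0.0)
        table = ds.reversal_scan(model, [100], [0.003])
        assert not table["integrable"].iloc[0]
        assert np.isnan(table["mass_above_half"].iloc[0])


class TestMutationSweep:
    def test_death_altruism_shape_sequence(self, death_altruism):
        """Rising mutation reshapes the density: U skewed toward the actor,
        then the low-turnover boundary (p = 1, where T/n is minimized) is
        pushed interior first, then fully unimodal."""
        table = ds.mutation_sweep(death_altruism, [2e-5, 2e-4, 0.006])
        low, mid, high = table.iloc[0], table.iloc[1], table.iloc[2]
        assert low["shape"] == "U" and low["mass_above_half"] > 0.5
        assert mid["shape"] == "boundary-unimodal" and mid["mass_above_half"] > 0.5
        assert high["shape"] == "bell"

    def test_stochastic_skew_shrinks_with_mutation(self, death_altruism):
        table = ds.mutation_sweep(death_altruism, [0.002, 0.006, 0.02, 0.06, 0.2])
        skew = np.abs(table["mass_above_half"].to_numpy() - 0.5)
        assert np.all(np.diff(skew) < 1e-12)


class TestMutationFixationChain:
    def test_transition_rate_independent_of_population_size(self):
        assert ds.monomorphic_transition_rate(1e-6, 600) == pytest.approx(1e-6)
        assert ds.monomorphic_transition_rate(1e-6, 10**6) == pytest.approx(1e-6)
        with pytest.raises(ValueError):
            ds.monomorphic_transition_rate(1e-6, 0)

    def test_symmetric_mutation_gives_uniform_occupancy(self):
        k = 5
        mu = np.full((k, k), 2.5e-7)
        pi = ds.trait_chain_stationary(mu)
        assert pi == pytest.approx(np.full(k, 1 / k), abs=1e-12)

    def test_biased_mutation_biases_occupancy(self):
        mu = np.array([[0.0, 1e-6], [3e-6, 0.0]])
        pi = ds.trait_chain_stationary(mu)
        # detailed balance: pi_0 mu_01 = pi_1 mu_10
        assert pi == pytest.approx([0.75, 0.25], abs=1e-12)


class TestInvasion:
    def test_hand_value_and_omega_scaling(self, death_neutral):
        prob = ds.invasion_probability_neutral(death_neutral, "non_actor")
        assert prob == pytest.approx(1 / 600, rel=1e-12)  # 1/(900 * 2/3)
        doubled = ds.invasion_probability_neutral(death_neutral.with_(omega=1800), "non_actor")
        assert doubled == pytest.approx(prob / 2, rel=1e-12)

    def test_altruism_asymmetry(self, death_altruism):
        """Altruism raises n(1) above n(0), so the actor invades more easily."""
        into_residents = ds.invasion_probability_neutral(death_altruism, "non_actor")
        into_actors = ds.invasion_probability_neutral(death_altruism, "actor")
        assert into_residents > into_actors
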