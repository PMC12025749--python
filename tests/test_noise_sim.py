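"""Noise protocols: Box-Muller multiplier, forward and trade-off variations."""

import math

import numpy as np
import pytest
from scipy import stats

from dissipath import (
    ReactionScheme,
    classify_reaction,
    draw_noise,
    find_max_dissipation,
    forward_variation_step,
    haldane_check,
    performance,
    run_forward_variations,
    run_tradeoff_variations,
    steady_state,
    tradeoff_transform,
)
from dissipath.cycle_models import master_equation_probabilities
from dissipath.noise_sim import _effective_g_sequence, noise_multiplier
from dissipath.synthetic_data import SchemeSamplerConfig, sample_scheme


class TestNoiseMultiplier:
    @pytest.mark.parametrize(
        "s1, s2, expected",
        [
            (math.exp(-2), 0.0, 3.0),  # sqrt(4)*cos(0) + 1
            (math.exp(-2), 0.5, -1.0),  # sqrt(4)*cos(pi) + 1
            (0.123, 0.25, 1.0),  # cos(pi/2) = 0 for any s1
            (0.879, 0.25, 1.0),
        ],
    )
    def test_hand_values(self, s1, s2, expected):
        assert noise_multiplier(s1, s2) == pytest.approx(expected, abs=1e-12)

    def test_shifted_multiplier_is_standard_normal(self):
        rng = np.random.default_rng(0)
        g = np.array([draw_noise(rng).g for _ in range(10_000)])
        assert stats.kstest(g - 1.0, "norm").pvalue > 0.01

    def test_replacement_rule_matches_naive_loop(self):
        # oracle: re-apply the rule step by step on the same uniform stream
        rng = np.random.default_rng(5)
        got = _effective_g_sequence(rng, 2000)
        rng = np.random.default_rng(5)
        raw = [noise_multiplier(*rng.random(2)) for _ in range(2000)]
        while raw[0] <= 0:
            raw[0] = draw_noise(rng).g
        expected = [raw[0]]
        for g in raw[1:]:
            expected.append(g if g > 0 else expected[-1])
        assert np.allclose(got, expected)
        assert (got > 0).all()


class TestForwardVariations:
    def test_identity_multiplier(self, three_state):
        assert forward_variation_step(three_state, 1.0) == three_state

    def test_doubling_scales_flux_not_force(self, two_state):
        sol = steady_state(forward_variation_step(two_state, 2.0))
        assert sol.flux == pytest.approx(0.4)
        assert sol.force_rt == pytest.approx(math.log(2))
        assert sol.dissipation_rt == pytest.approx(0.4 * math.log(2))

    def test_nonpositive_multiplier_rejected(self, two_state):
        with pytest.raises(ValueError):
            forward_variation_step(two_state, 0.0)

    def test_trace_invariants_and_linear_scaling(self, four_state):
        trace = run_forward_variations(four_state, n_steps=2000, seed=3)
        steps = trace.steps
        base = steps.iloc[0]
        for col in ["km", "force_rt", "entropy", "p1", "p2", "p3", "p4"]:
            assert np.allclose(steps[col], steps[col].iloc[0], rtol=1e-10)
        # maxima of kcat, efficiency and dissipation coincide at max g
        gmax = steps["g"].idxmax()
        assert steps["kcat"].idxmax() == gmax
        assert steps["efficiency"].idxmax() == gmax
        assert steps["dissipation_rt"].idxmax() == gmax == trace.argmax_step
        ratio = steps["dissipation_rt"] / steps["g"]
        assert np.allclose(ratio, ratio.iloc[0], rtol=1e-10)

    def test_efficiency_dissipation_regression_is_perfectly_linear(self, three_state):
        steps = run_forward_variations(three_state, n_steps=1000, seed=11).steps
        r = np.corrcoef(steps["dissipation_rt"], steps["efficiency"])[0, 1]
        assert r**2 == pytest.approx(1.0, abs=1e-10)
        slope = (
            steps["efficiency"].iloc[0] / steps["dissipation_rt"].iloc[0]
        )
        fitted = np.polyfit(steps["dissipation_rt"], steps["efficiency"], 1)[0]
        assert fitted == pytest.approx(slope, rel=1e-8)

    def test_maximum_amplification_matches_largest_multiplier(self, two_state):
        trace = run_forward_variations(two_state, n_steps=30000, seed=1)
        steps = trace.steps
        phi0 = steady_state(two_state).dissipation_rt
        assert steps["dissipation_rt"].max() / phi0 == pytest.approx(
            steps["g"].max(), rel=1e-10
        )
        # with ~N(1,1) multipliers and 30k steps the best factor is around 4-5
        assert 3.5 < steps["g"].max() < 6.5

    def test_reproducible_under_seed(self, two_state):
        a = run_forward_variations(two_state, n_steps=1000, seed=9).steps
        b = run_forward_variations(two_state, n_steps=1000, seed=9).steps
        assert a.equals(b)

    @pytest.mark.parametrize("bad_steps", [999, 30001])
    def test_step_budget_enforced(self, two_state, bad_steps):
        with pytest.raises(ValueError):
            run_forward_variations(two_state, n_steps=bad_steps)


class TestTradeoffTransform:
    def test_identity(self, three_state):
        assert tradeoff_transform(three_state, 1.0) == three_state

    def test_rates_mode_three_state_example(self, three_state):
        t = tradeoff_transform(three_state, 2.0, mode="rates")
        assert t.k == pytest.approx((4, 1, 1, 1, 0.5, 1))
        sol = steady_state(t)
        assert sol.force_rt == pytest.approx(math.log(2), abs=1e-12)
        # flux against the master-equation oracle on the transformed scheme
        p = master_equation_probabilities(t)
        assert sol.flux == pytest.approx(p[0] * t.k[0] - p[1] * t.k[1], rel=1e-10)

    @pytest.mark.parametrize("mode", ["rates", "reverse"])
    def test_force_and_haldane_preserved(self, four_state, mode):
        x0 = steady_state(four_state).force_rt
        for g in (0.037, 0.5, 3.0, 40.0):
            t = tradeoff_transform(four_state, g, mode=mode)
            assert steady_state(t).force_rt == pytest.approx(x0, abs=1e-12)
            assert haldane_check(t) < 1e-9

    def test_step_equilibrium_constants_shift_compensatorily(self, four_state):
        g = 2.5
        base = four_state.step_equilibrium_constants
        trans = tradeoff_transform(four_state, g).step_equilibrium_constants
        assert trans[0] == pytest.approx(g * base[0], rel=1e-12)
        assert trans[-1] == pytest.approx(base[-1] / g, rel=1e-12)
        assert trans[1:-1] == pytest.approx(base[1:-1], rel=1e-12)

    def test_unknown_mode_rejected(self, two_state):
        with pytest.raises(ValueError):
            tradeoff_transform(two_state, 2.0, mode="sideways")


class TestMaxDissipationSearch:
    def test_grid_dominates_stochastic_trace(self, three_state):
        grid = find_max_dissipation(three_state, method="grid")
        trace = run_tradeoff_variations(three_state, n_steps=5000, seed=4)
        assert grid.phi_max_rt >= trace.steps["dissipation_rt"].max() - 1e-12

    def test_methods_agree_on_sampled_schemes(self):
        for seed in range(5):
            s = sample_scheme(SchemeSamplerConfig(n_states=3, seed=200 + seed))
            grid = find_max_dissipation(s, method="grid")
            sto = find_max_dissipation(s, method="stochastic", budget=30000, seed=seed)
            assert not grid.boundary
            assert sto.phi_max_rt <= grid.phi_max_rt * (1 + 1e-9)
            assert sto.phi_max_rt == pytest.approx(grid.phi_max_rt, rel=0.01)

    def test_never_below_reference_state(self, four_state):
        for method in ("grid", "stochastic"):
            res = find_max_dissipation(four_state, method=method, budget=1000)
            assert res.phi_max_rt >= res.phi_observed_rt
            assert res.phi_observed_rt == pytest.approx(
                steady_state(four_state).dissipation_rt
            )

    def test_interior_maximum_exists_for_sampled_schemes(self, random_schemes):
        # dissipation declines toward both g extremes under the trade-off
        import numpy as np

        from dissipath.noise_sim import _phi_of_g

        sweep = np.logspace(-8, 8, 321)
        for n in (2, 3, 4):
            for s in random_schemes[n][:10]:
                phi = np.asarray(_phi_of_g(s, sweep, "rates"))
                peak = int(np.argmax(phi))
                assert 0 < peak < len(sweep) - 1
                assert phi[0] < phi[peak] and phi[-1] < phi[peak]

    def test_boundary_maximum_is_flagged(self):
        # substrate binding vastly faster than release pushes the optimum
        # below the search range
        s = ReactionScheme(2, (1e8, 1.0, 1e-4, 1e-3), 1e-3, 1e-4)
        with pytest.warns(UserWarning, match="boundary"):
            res = find_max_dissipation(s, method="grid")
        assert res.boundary

    def test_optimal_scheme_consistent_with_reported_value(self, three_state):
        res = find_max_dissipation(three_state, method="grid")
        assert steady_state(res.scheme).dissipation_rt == pytest.approx(
            res.phi_max_rt, rel=1e-9
        )


class TestClassification:
    def test_efficiency_gain_is_eff(self, three_state):
        obs = performance(three_state)
        opt = performance(tradeoff_transform(three_state, 2.0))
        if opt.efficiency > obs.efficiency:
            assert classify_reaction(obs, 1.0, opt, 2.0) == "Eff"

    def test_fold_semantics(self):
        obs = performance(ReactionScheme(2, (10, 1, 5, 1), 1e-3, 1e-4))
        better_eff = performance(ReactionScheme(2, (30, 1, 4, 1), 1e-3, 1e-4))
        assert better_eff.efficiency > obs.efficiency
        assert better_eff.kcat < obs.kcat
        assert classify_reaction(obs, 1.0, better_eff, 2.0) == "Eff"
        better_kcat = performance(ReactionScheme(2, (5, 1, 9, 1), 1e-3, 1e-4))
        assert better_kcat.kcat > obs.kcat
        assert classify_reaction(obs, 1.0, better_kcat, 2.0) == "Tur"

    def test_violated_implication_warns_but_classifies(self):
        obs = performance(ReactionScheme(2, (10, 1, 5, 1), 1e-3, 1e-4))
        both_up = performance(ReactionScheme(2, (30, 1, 9, 1), 1e-3, 1e-4))
        with pytest.warns(UserWarning, match="kcat"):
            assert classify_reaction(obs, 1.0, both_up, 2.0) == "Eff"

    def test_equal_efficiency_is_tur(self, two_state):
        obs = performance(two_state)
        with pytest.warns(UserWarning):
            assert classify_reaction(obs, 1.0, obs, 1.0) == "Tur"
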