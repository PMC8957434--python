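"""Moment-matched distributions, Monte Carlo PSA, acceptability curves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rfacea import (
    ParamSpec,
    WTPRule,
    assign_distributions,
    beta_from_mean_range,
    ceac,
    gamma_from_mean_range,
    icer,
    run_psa,
)
from rfacea.psa import decide_per_draw


class TestBetaFromMeanRange:
    def test_pfs_utility_parameters(self):
        """Mean 0.76 with range 0.61-0.91 read as a 95% interval."""
        a, b = beta_from_mean_range(0.76, 0.61, 0.91, "ci95")
        assert a == pytest.approx(22.91, abs=0.01)
        assert b == pytest.approx(7.23, abs=0.01)

    def test_symmetric_mean_gives_equal_shapes(self):
        a, b = beta_from_mean_range(0.5, 0.3, 0.7)
        assert a == pytest.approx(b)

    @given(
        mean=st.floats(0.05, 0.95),
        half=st.floats(0.01, 0.2),
        semantics=st.sampled_from(["ci95", "minmax"]),
    )
    @settings(max_examples=200, derandomize=True)
    def test_moment_round_trip(self, mean, half, semantics):
        low, high = mean - half, mean + half
        a, b = beta_from_mean_range(mean, low, high, semantics)
        assert a / (a + b) == pytest.approx(mean, abs=1e-12)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        divisor = 3.92 if semantics == "ci95" else np.sqrt(12)
        assert var == pytest.approx(((high - low) / divisor) ** 2, rel=1e-9)

    def test_infeasible_moments_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            beta_from_mean_range(0.01, 0.0, 0.5)

    def test_mean_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            beta_from_mean_range(1.2, 0.5, 1.5)


class TestGammaFromMeanRange:
    def test_follow_up_cost_parameters(self):
        """Mean $117.16 with the 50%-200% range $58.58-$234.32."""
        shape, scale = gamma_from_mean_range(117.16, 58.58, 234.32, "ci95")
        assert shape == pytest.approx(6.83, abs=0.01)
        assert scale == pytest.approx(17.16, abs=0.01)

    @given(mean=st.floats(1.0, 500.0), spread=st.floats(0.1, 1.5))
    @settings(max_examples=200, derandomize=True)
    def test_moment_round_trip(self, mean, spread):
        low, high = mean * (1 - spread / 2), mean * (1 + spread / 2)
        shape, scale = gamma_from_mean_range(mean, low, high)
        assert shape * scale == pytest.approx(mean, rel=1e-12)
        assert shape * scale**2 == pytest.approx(((high - low) / 3.92) ** 2, rel=1e-9)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            gamma_from_mean_range(0.0, -1.0, 1.0)


@pytest.fixture(scope="module")
def assignments(param_table):
    return assign_distributions(param_table, "ci95")


@pytest.fixture(scope="module")
def small_psa(base_scenario, assignments):
    return run_psa(base_scenario, assignments, n_draws=2000, seed=7)


class TestRunPsa:
    def test_all_fixed_collapses_to_base_case(self, base_scenario, param_table):
        fixed = [
            ParamSpec(p.name, p.base, p.low, p.high, "fixed", p.targets)
            for p in param_table
        ]
        samples = run_psa(base_scenario, assign_distributions(fixed), 20, seed=1)
        o23, o34 = base_scenario.outcomes()
        for s in samples:
            assert s.outcome_two_three.discounted_qaly == pytest.approx(o23.discounted_qaly)
            assert s.outcome_three_four.discounted_cost == pytest.approx(o34.discounted_cost)

    def test_fixed_seed_reproducible(self, base_scenario, assignments):
        a = run_psa(base_scenario, assignments, 50, seed=123)
        b = run_psa(base_scenario, assignments, 50, seed=123)
        assert a == b

    def test_sampled_utility_mean_matches_target(self, small_psa):
        """CLT check: the sampled PFS-utility mean sits within 3 SE of 0.76."""
        u = np.array([s.params["utility_pfs"] for s in small_psa])
        se = (0.91 - 0.61) / 3.92 / np.sqrt(len(u))
        assert abs(u.mean() - 0.76) < 3 * se

    def test_sampled_supports(self, small_psa):
        for s in small_psa[:200]:
            assert 0.0 <= s.params["p_two_three"] <= 1.0
            assert 0.0 <= s.params["utility_pfs"] <= 1.0
            assert s.params["cost_two_three"] >= 0.0
            assert s.params["discount_rate"] == 0.05  # fixed family

    def test_substreams_stable_under_parameter_addition(
        self, base_scenario, param_table
    ):
        """Appending a parameter must not perturb earlier parameters' draws."""
        short = assign_distributions(param_table[:3])
        extended = assign_distributions(list(param_table))
        a = run_psa(base_scenario, short, 30, seed=9)
        b = run_psa(base_scenario, extended, 30, seed=9)
        for sa, sb in zip(a, b):
            for name in ("p_two_three", "p_three_four", "cost_two_three"):
                assert sa.params[name] == sb.params[name]


class TestCeac:
    def test_curves_partition_probability(self, small_psa):
        for pt in ceac(small_psa, [0.0, 5000.0, 10888.0, 20000.0]):
            assert pt.prob_2_3_preferred + pt.prob_3_4_preferred == pytest.approx(1.0)

    def test_all_fixed_ceac_steps_at_base_icer(self, base_scenario, param_table):
        fixed = [
            ParamSpec(p.name, p.base, p.low, p.high, "fixed", p.targets)
            for p in param_table
        ]
        samples = run_psa(base_scenario, assign_distributions(fixed), 5, seed=1)
        o23, o34 = base_scenario.outcomes()
        base_icer = icer(o23, o34).icer
        below, at, above = ceac(samples, [base_icer - 1, base_icer, base_icer + 1])
        assert below.prob_2_3_preferred == 0.0
        assert at.prob_2_3_preferred == 0.0  # tie goes to the cheaper reference
        assert above.prob_2_3_preferred == 1.0

    def test_matches_per_draw_decision_rule(self, small_psa):
        subset = small_psa[:200]
        point = ceac(subset, [10888.0])[0]
        labels = decide_per_draw(subset, WTPRule(10888.0))
        assert point.prob_2_3_preferred == pytest.approx(
            labels.count("two_three_month") / len(labels)
        )

    def test_monotone_for_dearer_more_effective_strategy(self, small_psa):
        """Where the QALY gain is positive in every draw, the comparator's
        acceptability is non-decreasing in WTP."""
        gains = [
            s.outcome_two_three.discounted_qaly - s.outcome_three_four.discounted_qaly
            for s in small_psa
        ]
        subset = [s for s, g in zip(small_psa, gains) if g > 0]
        probs = [pt.prob_2_3_preferred for pt in ceac(subset, np.linspace(0, 2e4, 21))]
        assert all(b >= a - 1e-12 for a, b in zip(probs, probs[1:]))

    def test_empty_inputs_rejected(self, small_psa):
        with pytest.raises(ValueError):
            ceac([], [1.0])
        with pytest.raises(ValueError):
            ceac(small_psa, [])
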