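"""Two-state absorbing cohort model: traces, rewards, conventions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rfacea import (
    DiscountTiming,
    MarkovSpec,
    RewardTiming,
    StrategySpec,
    closed_form_pfs_months,
    discount_factor,
    run_cohort,
)


def strategy(p, cost=117.16, u=0.76, **kw):
    return StrategySpec("s", p, cost, utility_pfs=u, **kw)


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "t, expected",
        [(0, 1.0), (12, 1 / 1.05), (1, 1.05 ** (-1 / 12)), (24, 1 / 1.05**2)],
    )
    def test_continuous_monthly(self, t, expected):
        assert discount_factor(t, MarkovSpec()) == pytest.approx(expected, abs=1e-12)

    def test_annual_step_is_piecewise_constant(self):
        spec = MarkovSpec(discount_timing="annual_step")
        assert discount_factor(0, spec) == 1.0
        assert discount_factor(11, spec) == 1.0
        assert discount_factor(12, spec) == pytest.approx(1 / 1.05)
        assert discount_factor(23, spec) == pytest.approx(1 / 1.05)

    def test_negative_cycle_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1, MarkovSpec())


class TestRunCohort:
    def test_no_events_no_discount(self):
        model = MarkovSpec(annual_discount=0.0)
        trace, outcome = run_cohort(model, strategy(0.0))
        assert outcome.discounted_pfs_months == pytest.approx(24.0)
        assert np.all(trace.occupancy_pfs == 1.0)

    def test_certain_progression(self):
        _, outcome = run_cohort(MarkovSpec(), strategy(1.0))
        assert outcome.discounted_pfs_months <= 1.0
        assert outcome.discounted_qaly <= 0.76 / 12

    def test_base_case_closed_form_oracle(self):
        """End-of-cycle accumulation equals the geometric series r(1-r^24)/(1-r)."""
        _, outcome = run_cohort(MarkovSpec(), strategy(0.0118))
        r = (1 - 0.0118) * 1.05 ** (-1 / 12)
        expected = r * (1 - r**24) / (1 - r)
        assert outcome.discounted_pfs_months == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(19.785, abs=5e-4)

    def test_undiscounted_closed_form_example(self):
        assert closed_form_pfs_months(0.0251, 1.0, 24) == pytest.approx(17.738, abs=5e-4)

    def test_trace_matches_closed_form_on_random_inputs(self):
        """Oracle equivalence over 1000 random (p, discount) pairs."""
        rng = np.random.default_rng(11)
        for p, d in zip(rng.uniform(0, 0.9, 1000), rng.uniform(0, 0.15, 1000)):
            model = MarkovSpec(annual_discount=d)
            _, outcome = run_cohort(model, strategy(p))
            m = (1 + d) ** (-1 / 12)
            assert outcome.discounted_pfs_months == pytest.approx(
                closed_form_pfs_months(p, m, 24), abs=1e-9
            )

    def test_outcome_reward_identities(self):
        """Cost and QALYs are exact multiples of discounted PFS-months."""
        _, o = run_cohort(MarkovSpec(), strategy(0.0251, cost=78.10))
        assert o.discounted_cost == pytest.approx(o.discounted_pfs_months * 78.10)
        assert o.discounted_qaly == pytest.approx(o.discounted_pfs_months * 0.76 / 12)

    @given(
        p=st.floats(0.0, 1.0),
        d=st.floats(0.0, 0.3),
        horizon=st.integers(1, 60),
    )
    @settings(max_examples=200, derandomize=True)
    def test_mass_conservation(self, p, d, horizon):
        model = MarkovSpec(horizon_cycles=horizon, annual_discount=d)
        trace, _ = run_cohort(model, strategy(p))
        np.testing.assert_allclose(trace.occupancy_pfs + trace.occupancy_pd, 1.0, atol=1e-12)
        assert np.all(np.diff(trace.occupancy_pfs) <= 1e-15)

    def test_monotone_in_p_and_discount(self):
        base = run_cohort(MarkovSpec(), strategy(0.0118))[1]
        worse_p = run_cohort(MarkovSpec(), strategy(0.02))[1]
        more_disc = run_cohort(MarkovSpec(annual_discount=0.1), strategy(0.0118))[1]
        assert worse_p.discounted_qaly < base.discounted_qaly
        assert worse_p.discounted_cost < base.discounted_cost
        assert more_disc.discounted_qaly < base.discounted_qaly

    @pytest.mark.parametrize("p", [0.0118, 0.0251, 0.3])
    def test_convention_bracketing(self, p):
        """start_of_cycle >= half_cycle >= end_of_cycle accumulation."""
        months = {}
        for rt in RewardTiming:
            model = MarkovSpec(reward_timing=rt)
            months[rt] = run_cohort(model, strategy(p))[1].discounted_pfs_months
        assert (
            months[RewardTiming.START_OF_CYCLE]
            >= months[RewardTiming.HALF_CYCLE]
            >= months[RewardTiming.END_OF_CYCLE]
        )

    def test_half_cycle_is_trapezoid_mean(self):
        spec_end = MarkovSpec(reward_timing="end_of_cycle")
        spec_start = MarkovSpec(reward_timing="start_of_cycle")
        spec_half = MarkovSpec(reward_timing="half_cycle")
        s = strategy(0.05)
        m_end = run_cohort(spec_end, s)[1].discounted_pfs_months
        m_start = run_cohort(spec_start, s)[1].discounted_pfs_months
        m_half = run_cohort(spec_half, s)[1].discounted_pfs_months
        assert m_half == pytest.approx(0.5 * (m_end + m_start), abs=1e-12)

    def test_pd_utility_variant_accrues_in_absorbing_state(self):
        base = run_cohort(MarkovSpec(), strategy(0.1))[1]
        with_pd = run_cohort(MarkovSpec(pd_accrues_utility=True), strategy(0.1))[1]
        assert with_pd.discounted_qaly > base.discounted_qaly
        assert with_pd.discounted_cost == pytest.approx(base.discounted_cost)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            StrategySpec("s", 1.2, 100.0)

    def test_trace_export_columns(self):
        trace, _ = run_cohort(MarkovSpec(), strategy(0.0118))
        df = trace.to_frame()
        assert list(df.columns) == [
            "cycle", "occupancy_pfs", "occupancy_pd", "discount", "cost", "qaly",
        ]
        assert len(df) == 25  # cycles 0..24


class TestClosedForm:
    def test_no_events_no_discount(self):
        assert closed_form_pfs_months(0.0, 1.0, 24) == pytest.approx(24.0)

    def test_certain_progression_safe(self):
        assert closed_form_pfs_months(1.0, 0.995, 24) == 0.0

    def test_near_unity_ratio_falls_back_to_direct_sum(self):
        assert closed_form_pfs_months(0.0, 1.0 - 1e-15, 24) == pytest.approx(24.0, abs=1e-9)
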