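"""Cohort engine: matrix assembly, trace propagation, discounting, rewards."""

import numpy as np
import pytest

from gdcea.model_core import (
    CohortTrace,
    CycleRewards,
    DiscountSpec,
    TimeGrid,
    TransitionMatrix,
    accumulate_outcomes,
    build_transition_matrix,
    discount_factors,
    run_cohort,
)

STATES2 = ("alive", "death")
ADJ2 = {("alive", "alive"), ("alive", "death"), ("death", "death")}


def two_state_matrix(p_death: float) -> TransitionMatrix:
    return build_transition_matrix([("alive", "death", p_death)], ADJ2, STATES2)


class TestBuildTransitionMatrix:
    def test_empty_entries_give_identity(self):
        states = tuple("abcdefg") + ("death",)
        adj = {(s, t) for s in states for t in states}
        m = build_transition_matrix([], adj, states)
        assert np.array_equal(m.probs, np.eye(8))

    def test_all_mass_to_death_yields_unit_death_column(self):
        states = ("a", "b", "death")
        adj = {(s, t) for s in states for t in states}
        entries = [("a", "death", 1.0), ("b", "death", 1.0)]
        m = build_transition_matrix(entries, adj, states)
        assert np.allclose(m.probs[:, 2], 1.0)

    def test_overspecified_row_raises(self):
        states = ("a", "b", "death")
        adj = {(s, t) for s in states for t in states}
        with pytest.raises(ValueError, match="over-specified"):
            build_transition_matrix(
                [("a", "death", 0.6), ("a", "b", 0.5)], adj, states
            )

    def test_adjacency_violation_and_duplicates_rejected(self):
        states = ("a", "b", "death")
        adj = {("a", "a"), ("b", "b"), ("death", "death"), ("a", "death"),
               ("b", "death")}
        with pytest.raises(ValueError, match="adjacency"):
            build_transition_matrix([("a", "b", 0.1)], adj, states)
        with pytest.raises(ValueError, match="duplicate"):
            build_transition_matrix(
                [("a", "death", 0.1), ("a", "death", 0.2)], adj, states
            )

    def test_diagonal_closure_preserves_row_sums(self):
        m = two_state_matrix(0.25)
        assert m.probs[0, 0] == pytest.approx(0.75)
        assert np.allclose(m.probs.sum(axis=1), 1.0)


class TestRunCohort:
    def test_identity_matrix_constant_trace(self):
        states = tuple("abcdefg") + ("death",)
        adj = {(s, t) for s in states for t in states}
        m = build_transition_matrix([], adj, states)
        init = np.zeros(8)
        init[0] = 1.0
        trace = run_cohort(m, init, TimeGrid())
        assert trace.occupancy.shape == (73, 8)
        assert np.allclose(trace.occupancy, init)

    def test_geometric_survival_closed_form(self):
        # alive -> death at 0.1/cycle: alive occupancy is 0.9^t exactly
        trace = run_cohort(two_state_matrix(0.1), np.array([1.0, 0.0]), TimeGrid())
        t = np.arange(73)
        assert np.allclose(trace.occupancy[:, 0], 0.9 ** t, atol=1e-12)

    def test_everyone_dies_in_first_cycle(self):
        trace = run_cohort(two_state_matrix(1.0), np.array([1.0, 0.0]), TimeGrid())
        assert trace.occupancy[1, 1] == pytest.approx(1.0)

    def test_bad_initial_distribution_rejected(self):
        m = two_state_matrix(0.1)
        with pytest.raises(ValueError):
            run_cohort(m, np.array([0.5, 0.2]), TimeGrid())
        with pytest.raises(ValueError):
            run_cohort(m, np.array([1.0, 0.0, 0.0]), TimeGrid())


class TestDiscountFactors:
    def test_zero_rate_is_all_ones(self):
        d = discount_factors(DiscountSpec(0.0), TimeGrid())
        assert np.array_equal(d, np.ones(72))

    def test_closed_form_values(self):
        d = discount_factors(DiscountSpec(0.05), TimeGrid())
        assert d[11] == pytest.approx(1 / 1.05, abs=1e-12)  # end of year 1
        assert d[71] == pytest.approx(1.05 ** -6, abs=1e-12)  # end of year 6


class TestAccumulateOutcomes:
    def _rewards(self, cost, utility):
        return CycleRewards(
            states=STATES2,
            state_cost_per_cycle=np.array([cost, 0.0]),
            state_utility=np.array([utility, 0.0]),
        )

    def test_zero_rewards_zero_totals(self):
        trace = run_cohort(two_state_matrix(0.1), np.array([1.0, 0.0]), TimeGrid())
        c, q = accumulate_outcomes(
            trace, self._rewards(0.0, 0.0), DiscountSpec(0.05), TimeGrid()
        )
        assert c == 0.0 and q == 0.0

    def test_immortal_full_utility_equals_horizon(self):
        trace = run_cohort(two_state_matrix(0.0), np.array([1.0, 0.0]), TimeGrid())
        _, q = accumulate_outcomes(
            trace, self._rewards(0.0, 1.0), DiscountSpec(0.0), TimeGrid()
        )
        assert q == pytest.approx(6.0, abs=1e-12)

    def test_matches_per_cycle_hand_summation(self):
        # independent brute-force oracle: explicit per-cycle loop
        p, utility, cost, rate = 0.1, 0.86, 1000.0, 0.05
        grid = TimeGrid()
        trace = run_cohort(two_state_matrix(p), np.array([1.0, 0.0]), grid)
        exp_cost = exp_qalys = 0.0
        for t in range(1, 73):
            alive_start = 0.9 ** (t - 1)
            alive_end = 0.9 ** t
            eff = 0.5 * (alive_start + alive_end)
            d = (1 + rate) ** (-t / 12)
            exp_cost += d * eff * cost
            exp_qalys += d * eff * utility / 12
        c, q = accumulate_outcomes(
            trace, self._rewards(cost, utility), DiscountSpec(rate), grid
        )
        assert c == pytest.approx(exp_cost, abs=1e-9)
        assert q == pytest.approx(exp_qalys, abs=1e-9)

    def test_half_cycle_bracketed_by_start_and_end_weighting(self):
        grid = TimeGrid()
        trace = run_cohort(two_state_matrix(0.08), np.array([1.0, 0.0]), grid)
        rewards = self._rewards(500.0, 0.7)
        spec = DiscountSpec(0.05)
        totals = {
            w: accumulate_outcomes(trace, rewards, spec, grid, weighting=w)
            for w in ("cycle_start", "half_cycle", "cycle_end")
        }
        for i in range(2):  # cost then QALYs
            lo = min(totals["cycle_start"][i], totals["cycle_end"][i])
            hi = max(totals["cycle_start"][i], totals["cycle_end"][i])
            assert lo <= totals["half_cycle"][i] <= hi

    def test_totals_non_increasing_in_discount_rate(self):
        grid = TimeGrid()
        trace = run_cohort(two_state_matrix(0.05), np.array([1.0, 0.0]), grid)
        rewards = self._rewards(1000.0, 0.86)
        prev = None
        for rate in (0.0, 0.02, 0.05, 0.10):
            totals = accumulate_outcomes(trace, rewards, DiscountSpec(rate), grid)
            if prev is not None:
                assert totals[0] <= prev[0] and totals[1] <= prev[1]
            prev = totals

    def test_qalys_bounded_by_horizon_times_max_utility(self):
        grid = TimeGrid()
        trace = run_cohort(two_state_matrix(0.02), np.array([1.0, 0.0]), grid)
        _, q = accumulate_outcomes(
            trace, self._rewards(0.0, 0.86), DiscountSpec(0.0), grid
        )
        assert q <= 6.0 * 0.86 + 1e-12
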