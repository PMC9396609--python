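"""Occupancy-measure LP: structure, solutions, policy recovery, oracle parity."""

import numpy as np
import pytest

from carecost import (
    CostSchedule,
    DecisionSpace,
    DecisionTransitionSet,
    EnumerationSizeError,
    StateSpace,
    build_lp,
    compute_effective_matrix,
    enumerate_pure_policies,
    expected_cost_deterministic,
    marginal_theta,
    recover_conditional_policy,
    solve_randomized,
    stationary_distribution,
)
from carecost import example as ex
from conftest import random_mdp_instance


@pytest.fixture(scope="module")
def cardiac_lp():
    space = ex.cardiac_state_space()
    decisions = ex.cardiac_decision_space()
    x = compute_effective_matrix(
        ex.cardiac_accuracy(), ex.cardiac_raw_transitions(), space
    )
    transitions = DecisionTransitionSet.shared(x, decisions)
    return build_lp(space, decisions, ex.cardiac_randomized_costs(), transitions)


class TestBuildLp:
    def test_cardiac_structure_counts(self, cardiac_lp):
        assert cardiac_lp.n_variables == 11
        assert cardiac_lp.n_equalities == 5  # 1 normalisation + 4 balance
        assert cardiac_lp.n_bound_constraints == 22

    def test_three_state_two_decision_counts(self):
        rng = np.random.default_rng(0)
        space, decisions, costs, transitions = random_mdp_instance(rng, 3, 2)
        lp = build_lp(space, decisions, costs, transitions)
        assert (lp.n_variables, lp.n_equalities, lp.n_bound_constraints) == (6, 4, 12)

    def test_variables_are_admissible_pairs_only(self, cardiac_lp):
        decisions = ex.cardiac_decision_space()
        assert set(cardiac_lp.variables) == set(decisions.admissible)

    def test_objective_at_reported_basis(self, cardiac_lp):
        value = cardiac_lp.objective_value(ex.reported_occupancy_indices())
        assert value == pytest.approx(3031.00, abs=1e-9)


class TestSolveRandomized:
    def test_single_decision_per_state_is_forced_to_theta(self):
        space = ex.cardiac_state_space()
        x = compute_effective_matrix(
            ex.cardiac_accuracy(), ex.cardiac_raw_transitions(), space
        )
        decisions = DecisionSpace(("only",), frozenset((0, m) for m in range(4)))
        lp = build_lp(
            space,
            decisions,
            ex.cardiac_cost_schedule(),
            DecisionTransitionSet.shared(x, decisions),
        )
        sol = solve_randomized(lp)
        theta = stationary_distribution(x)
        np.testing.assert_allclose(sol.theta.theta, theta.theta, atol=1e-8)
        assert sol.objective == pytest.approx(
            expected_cost_deterministic(theta, ex.cardiac_cost_schedule()), abs=1e-6
        )

    def test_state_only_costs_make_choice_irrelevant(self, cardiac_lp):
        """With shared transitions and state-only costs E_rand = E_det."""
        space = ex.cardiac_state_space()
        decisions = ex.cardiac_decision_space()
        x = compute_effective_matrix(
            ex.cardiac_accuracy(), ex.cardiac_raw_transitions(), space
        )
        lp = build_lp(
            space,
            decisions,
            ex.cardiac_cost_schedule(),  # no pair overrides
            DecisionTransitionSet.shared(x, decisions),
        )
        sol = solve_randomized(lp)
        e_det = expected_cost_deterministic(
            stationary_distribution(x), ex.cardiac_cost_schedule()
        )
        assert sol.objective == pytest.approx(e_det, rel=1e-8)

    def test_occupancy_sums_to_one_and_residuals_small(self, cardiac_lp):
        sol = solve_randomized(cardiac_lp)
        assert sum(sol.y.values()) == pytest.approx(1.0, abs=1e-8)
        assert sol.residual <= 1e-8
        assert all(0.0 <= v <= 1.0 for v in sol.y.values())

    def test_solution_is_reproducible(self, cardiac_lp):
        a = solve_randomized(cardiac_lp)
        b = solve_randomized(cardiac_lp)
        assert a.y == b.y and a.objective == b.objective

    def test_policy_consistency_y_equals_theta_times_d(self, cardiac_lp):
        sol = solve_randomized(cardiac_lp)
        for (k, m), y_val in sol.y.items():
            d = sol.policy[(k, m)]
            if d is not None:
                assert y_val == pytest.approx(sol.theta.theta[m] * d, abs=1e-8)


class TestPolicyRecovery:
    def test_reported_basis_policy(self):
        y = ex.reported_occupancy_indices()
        policy, undefined = recover_conditional_policy(y)
        assert policy[(0, 0)] == pytest.approx(1.0)
        assert policy[(1, 1)] == pytest.approx(1.0)
        assert policy[(3, 2)] == pytest.approx(0.097 / 0.532)  # approx 0.182
        assert policy[(2, 2)] == pytest.approx(0.435 / 0.532)
        assert policy[(4, 3)] == pytest.approx(1.0)
        assert undefined == []

    def test_even_split(self):
        policy, _ = recover_conditional_policy({(0, 0): 0.1, (1, 0): 0.1})
        assert policy[(0, 0)] == pytest.approx(0.5)
        assert policy[(1, 0)] == pytest.approx(0.5)

    def test_zero_mass_state_marked_undefined(self):
        policy, undefined = recover_conditional_policy(
            {(0, 0): 1.0, (0, 1): 0.0}, n_states=2
        )
        assert policy[(0, 1)] is None
        assert undefined == [1]

    def test_marginals_of_reported_basis(self):
        theta = marginal_theta(ex.reported_occupancy_indices(), n_states=4)
        np.testing.assert_allclose(theta.theta, [0.136, 0.215, 0.532, 0.117], atol=1e-12)


class TestEnumerationOracle:
    def test_two_decision_instance_picks_cheaper_everywhere(self):
        space = StateSpace(("a", "b"))
        decisions = DecisionSpace(
            ("d1", "d2"), frozenset((k, m) for k in range(2) for m in range(2))
        )
        chain = np.array([[0.5, 0.5], [1.0, 0.0]])
        transitions = DecisionTransitionSet({0: chain, 1: chain})
        costs = CostSchedule(
            np.zeros(2), pair_costs={(0, 0): 1, (0, 1): 2, (1, 0): 2, (1, 1): 1}
        )
        best = enumerate_pure_policies(space, decisions, costs, transitions)
        assert best.policy == {0: 0, 1: 1}

    def test_single_decision_equals_deterministic_cost(self):
        space = ex.cardiac_state_space()
        x = compute_effective_matrix(
            ex.cardiac_accuracy(), ex.cardiac_raw_transitions(), space
        )
        decisions = DecisionSpace(("only",), frozenset((0, m) for m in range(4)))
        best = enumerate_pure_policies(
            space,
            decisions,
            ex.cardiac_cost_schedule(),
            DecisionTransitionSet.shared(x, decisions),
        )
        e_det = expected_cost_deterministic(
            stationary_distribution(x), ex.cardiac_cost_schedule()
        )
        assert best.cost == pytest.approx(e_det, rel=1e-10)

    def test_lp_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            n_states = int(rng.integers(2, 5))
            n_decisions = int(rng.integers(1, 4))
            space, decisions, costs, transitions = random_mdp_instance(
                rng, n_states, n_decisions
            )
            lp = build_lp(space, decisions, costs, transitions)
            sol = solve_randomized(lp)
            best = enumerate_pure_policies(space, decisions, costs, transitions)
            assert sol.objective == pytest.approx(best.cost, abs=1e-6)
            assert sol.objective <= best.cost + 1e-6

    def test_enumeration_guard(self):
        rng = np.random.default_rng(1)
        space, decisions, costs, transitions = random_mdp_instance(rng, 4, 3)
        with pytest.raises(EnumerationSizeError):
            enumerate_pure_policies(space, decisions, costs, transitions, limit=10)
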