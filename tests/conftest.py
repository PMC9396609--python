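"""Shared fixtures: the cardiac case-study inputs and random-instance helpers."""

from __future__ import annotations

import numpy as np
import pytest

from carecost import (
    CostSchedule,
    DecisionSpace,
    DecisionTransitionSet,
    StateSpace,
)
from carecost import example as ex


@pytest.fixture(scope="session")
def cardiac_space():
    return ex.cardiac_state_space()


@pytest.fixture(scope="session")
def cardiac_decisions():
    return ex.cardiac_decision_space()


@pytest.fixture(scope="session")
def cardiac_accuracy():
    return ex.cardiac_accuracy()


@pytest.fixture(scope="session")
def cardiac_raw():
    return ex.cardiac_raw_transitions()


@pytest.fixture(scope="session")
def cardiac_costs():
    return ex.cardiac_cost_schedule()


def power_iteration(p: np.ndarray, tol: float = 1e-14, max_iter: int = 2_000_000):
    """Independent stationary-distribution oracle: iterate theta' P."""
    n = p.shape[0]
    theta = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = theta @ p
        nxt /= nxt.sum()
        if np.max(np.abs(nxt - theta)) < tol:
            return nxt
        theta = nxt
    raise AssertionError("power iteration did not converge")


def random_progression_chain(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random upper-triangular row-stochastic chain with a reset last row.

    All feasible entries positive, so the chain is irreducible.
    """
    p = np.zeros((n, n))
    for i in range(n - 1):
        support = n - i
        p[i, i:] = rng.dirichlet(np.ones(support) * 2.0)
        p[i, i:] += 1e-6  # keep entries strictly positive
        p[i] /= p[i].sum()
    p[n - 1, 0] = 1.0
    return p


def random_mdp_instance(rng: np.random.Generator, n_states: int, n_decisions: int):
    """Random small MDP: per-decision progression chains, all pairs admissible,
    independent pair costs."""
    space = StateSpace(tuple(f"s{i}" for i in range(n_states)))
    decisions = DecisionSpace(
        tuple(f"d{k}" for k in range(n_decisions)),
        frozenset((k, m) for k in range(n_decisions) for m in range(n_states)),
    )
    mats = {k: random_progression_chain(rng, n_states) for k in range(n_decisions)}
    transitions = DecisionTransitionSet(mats)
    pair_costs = {
        (k, m): float(rng.uniform(10, 1000))
        for k in range(n_decisions)
        for m in range(n_states)
    }
    costs = CostSchedule(np.full(n_states, np.nan), pair_costs=pair_costs)
    return space, decisions, costs, transitions
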