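"""Randomized treatment policy via the occupancy-measure linear program.

For an average-cost Markov decision process over states ``m`` and
admissible decisions ``k``, the steady-state *unconditional* (joint)
probabilities ``y(k, m) = P(state = m and decision = k)`` satisfy

* normalisation:   ``sum_{k,m} y(k, m) = 1``
* balance (per m): ``sum_k y(k, m) - sum_{m'} sum_k y(k, m') P_k[m', m] = 0``
* bounds:          ``0 <= y(k, m) <= 1``

Minimising ``sum c(k, m) y(k, m)`` over this polytope yields the
optimal *randomized* stationary policy; the conditional decision rule
is recovered as ``D(k, m) = y(k, m) / sum_k y(k, m)``.  A classical MDP
fact — the optimum is attained at a pure (deterministic per-state)
policy — gives an independent enumeration oracle for small instances.

One balance row is linearly dependent on the others together with the
normalisation; it is kept in the constraint matrix (HiGHS handles the
redundancy), which also matches the conventional functional-constraint
count of ``M + 2`` when that redundant row is included.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

from .core import CostSchedule, DecisionSpace, EffectiveTransitionMatrix, StateSpace
from .errors import EnumerationSizeError, StructuralError
from .markov import StationaryDistribution, stationary_distribution

__all__ = [
    "DecisionTransitionSet",
    "LinearProgram",
    "RandomizedSolution",
    "build_lp",
    "solve_randomized",
    "recover_conditional_policy",
    "marginal_theta",
    "enumerate_pure_policies",
    "PurePolicyResult",
]

_EQ_TOL = 1e-8


@dataclass(frozen=True)
class DecisionTransitionSet:
    """One row-stochastic transition matrix per decision.

    The baseline model has no decision-dependent dynamics — every
    decision shares the effective matrix ``x`` (use :meth:`shared`).
    Decision-dependent matrices are accepted as explicit input.
    """

    matrices: Mapping[int, np.ndarray]

    def __post_init__(self) -> None:
        mats = {}
        for k, m in self.matrices.items():
            arr = np.asarray(m, dtype=float)
            if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
                raise StructuralError(f"transition matrix for decision {k} not square")
            if np.any(np.abs(arr.sum(axis=1) - 1.0) > 1e-6):
                raise StructuralError(
                    f"transition matrix for decision {k} is not row-stochastic"
                )
            mats[int(k)] = arr
        sizes = {a.shape[0] for a in mats.values()}
        if len(sizes) > 1:
            raise StructuralError(f"mixed matrix sizes {sorted(sizes)}")
        object.__setattr__(self, "matrices", mats)

    @classmethod
    def shared(
        cls, x: EffectiveTransitionMatrix | np.ndarray, decisions: DecisionSpace
    ) -> "DecisionTransitionSet":
        arr = x.values if isinstance(x, EffectiveTransitionMatrix) else np.asarray(x, float)
        return cls({k: arr for k in range(decisions.n_decisions)})

    def matrix(self, k: int) -> np.ndarray:
        try:
            return self.matrices[k]
        except KeyError:
            raise StructuralError(f"no transition matrix for decision {k}") from None


@dataclass(frozen=True)
class LinearProgram:
    """Occupancy-measure LP over the admissible (decision, state) pairs.

    ``variables`` lists the pairs in (state, decision) order; bounds
    ``0 <= y <= 1`` are counted as two "soft" constraints per variable
    in reports, alongside the equality ("hard") constraints.
    """

    variables: tuple[tuple[int, int], ...]  # (decision, state)
    costs: np.ndarray
    a_eq: np.ndarray
    b_eq: np.ndarray
    states: tuple[str, ...]
    decisions: tuple[str, ...]

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def n_equalities(self) -> int:
        return self.a_eq.shape[0]

    @property
    def n_bound_constraints(self) -> int:
        return 2 * self.n_variables

    def index(self, decision: int, state: int) -> int:
        return self.variables.index((decision, state))

    def objective_value(self, y: Mapping[tuple[int, int], float] | np.ndarray) -> float:
        """Evaluate ``sum c(k, m) y(k, m)`` at an occupancy assignment.

        ``y`` may be a dense vector in variable order or a mapping from
        (decision, state) pairs; pairs absent from the mapping count as 0.
        """
        if isinstance(y, Mapping):
            vec = np.zeros(self.n_variables)
            for (k, m), val in y.items():
                vec[self.index(k, m)] = val
        else:
            vec = np.asarray(y, dtype=float)
        return float(self.costs @ vec)


def build_lp(
    space: StateSpace,
    decisions: DecisionSpace,
    costs: CostSchedule,
    transitions: DecisionTransitionSet,
) -> LinearProgram:
    """Assemble the occupancy LP: objective, one normalisation equality,
    and one balance equality per state.

    Cost coefficients are ``c(k, m)``: the pair override when present,
    else the state cost (raising :class:`~carecost.errors.ConfigError`
    when neither exists).
    """
    decisions.require_state_coverage(space)
    costs.require_admissible(decisions)
    variables = tuple(decisions.sorted_pairs())
    n = len(variables)
    m_states = space.n_states
    c = np.array([costs.cost(k, m) for k, m in variables])

    a_eq = np.zeros((1 + m_states, n))
    b_eq = np.zeros(1 + m_states)
    a_eq[0, :] = 1.0
    b_eq[0] = 1.0
    for j, (k, m_from) in enumerate(variables):
        p_k = transitions.matrix(k)
        if p_k.shape[0] != m_states:
            raise StructuralError(
                f"decision {decisions.decisions[k]!r} matrix size {p_k.shape[0]} "
                f"does not match the {m_states}-state space"
            )
        a_eq[1 + m_from, j] += 1.0
        for m_to in range(m_states):
            a_eq[1 + m_to, j] -= p_k[m_from, m_to]
    return LinearProgram(
        variables, c, a_eq, b_eq, states=space.states, decisions=decisions.decisions
    )


@dataclass(frozen=True)
class RandomizedSolution:
    """Optimal occupancy measure with recovered policy and marginals.

    ``policy[(k, m)]`` is the conditional probability ``D(k, m)`` of
    taking decision ``k`` in state ``m``; states carrying zero
    steady-state mass have ``None`` entries (the conditional is 0/0
    there) and are listed in ``undefined_states``.
    """

    y: dict[tuple[int, int], float]
    theta: StationaryDistribution
    policy: dict[tuple[int, int], float | None]
    objective: float
    residual: float
    undefined_states: tuple[int, ...] = field(default_factory=tuple)


def solve_randomized(lp: LinearProgram) -> RandomizedSolution:
    """Solve the occupancy LP with HiGHS and deterministic tie-breaking.

    Among alternative optima the solution minimising a fixed geometric
    secondary objective over the (state, decision)-ordered variables is
    returned, so reruns and equivalent formulations give the same basis.
    Infeasibility raises :class:`StructuralError` (it indicates an
    inconsistent transition/admissibility input); unboundedness cannot
    occur on the occupancy polytope and is reported as an internal error.
    """
    bounds = [(0.0, 1.0)] * lp.n_variables
    res = linprog(lp.costs, A_eq=lp.a_eq, b_eq=lp.b_eq, bounds=bounds, method="highs")
    if res.status == 2:
        raise StructuralError(
            "occupancy LP infeasible: transition matrices and admissibility "
            "are inconsistent"
        )
    if res.status == 3:  # pragma: no cover - impossible on a bounded polytope
        raise RuntimeError("internal error: occupancy LP reported unbounded")
    if not res.success:  # pragma: no cover - solver failure
        raise RuntimeError(f"LP solver failed: {res.message}")
    y_vec = res.x
    objective = float(lp.costs @ y_vec)

    # Tie-break: re-solve restricted to the optimal face with a fixed
    # geometric secondary objective.  Falls back to the first solution
    # if the restricted solve struggles numerically.
    weights = np.power(0.5, np.arange(lp.n_variables))
    res2 = linprog(
        weights,
        A_eq=lp.a_eq,
        b_eq=lp.b_eq,
        A_ub=lp.costs[None, :],
        b_ub=[objective + 1e-9 * max(1.0, abs(objective))],
        bounds=bounds,
        method="highs",
    )
    if res2.success and float(lp.costs @ res2.x) <= objective + 1e-6 * max(1.0, abs(objective)):
        y_vec = res2.x
        objective = float(lp.costs @ y_vec)

    residual = float(np.max(np.abs(lp.a_eq @ y_vec - lp.b_eq)))
    if residual > _EQ_TOL:
        raise RuntimeError(f"LP equality residual {residual:.3g} exceeds {_EQ_TOL:g}")
    y_vec = np.clip(y_vec, 0.0, 1.0)
    y = {pair: float(v) for pair, v in zip(lp.variables, y_vec)}
    theta = marginal_theta(y, n_states=len(lp.states), states=lp.states)
    policy, undefined = recover_conditional_policy(y, n_states=len(lp.states))
    return RandomizedSolution(
        y=y,
        theta=theta,
        policy=policy,
        objective=objective,
        residual=residual,
        undefined_states=tuple(undefined),
    )


def recover_conditional_policy(
    y: Mapping[tuple[int, int], float], n_states: int | None = None
) -> tuple[dict[tuple[int, int], float | None], list[int]]:
    """Conditional decision rule ``D(k, m) = y(k, m) / sum_k y(k, m)``.

    States with zero total occupancy get explicit ``None`` markers (the
    conditional probability is undefined there, not zero) and are
    returned in the second element.
    """
    states = sorted({m for _, m in y}) if n_states is None else range(n_states)
    totals = {m: 0.0 for m in states}
    for (k, m), val in y.items():
        totals[m] = totals.get(m, 0.0) + val
    policy: dict[tuple[int, int], float | None] = {}
    undefined = [m for m, tot in totals.items() if tot <= 0.0]
    for (k, m), val in y.items():
        policy[(k, m)] = None if totals[m] <= 0.0 else val / totals[m]
    return policy, sorted(undefined)


def marginal_theta(
    y: Mapping[tuple[int, int], float],
    n_states: int | None = None,
    states: tuple[str, ...] | None = None,
) -> StationaryDistribution:
    """Per-state marginals ``theta(m) = sum_k y(k, m)`` of an occupancy measure."""
    if n_states is None:
        n_states = max(m for _, m in y) + 1
    theta = np.zeros(n_states)
    for (_, m), val in y.items():
        theta[m] += val
    return StationaryDistribution(theta, states=states)


@dataclass(frozen=True)
class PurePolicyResult:
    """Best deterministic per-state decision assignment and its long-run cost."""

    policy: dict[int, int]  # state -> decision
    cost: float
    theta: StationaryDistribution


def enumerate_pure_policies(
    space: StateSpace,
    decisions: DecisionSpace,
    costs: CostSchedule,
    transitions: DecisionTransitionSet,
    limit: int = 10_000,
) -> PurePolicyResult:
    """Brute-force oracle over all pure policies.

    For each assignment ``m -> k`` of an admissible decision to every
    state, the induced chain takes row ``m`` from ``P_{k}``; its
    stationary distribution prices the policy at
    ``sum_m c(pi(m), m) theta_pi(m)``.  Returns the cheapest policy
    (first in lexicographic order on ties).  Assignments whose induced
    chain has no unique stationary distribution are skipped.  Guarded
    to at most ``limit`` assignments.
    """
    decisions.require_state_coverage(space)
    per_state = [decisions.decisions_for_state(m) for m in range(space.n_states)]
    total = int(np.prod([len(opts) for opts in per_state]))
    if total > limit:
        raise EnumerationSizeError(
            f"{total} pure policies exceed the enumeration guard of {limit}"
        )
    best: PurePolicyResult | None = None
    n = space.n_states
    for assignment in itertools.product(*per_state):
        p = np.vstack([transitions.matrix(assignment[m])[m] for m in range(n)])
        try:
            theta = stationary_distribution(p, states=space.states)
        except Exception:
            continue  # no unique long-run occupancy under this assignment
        cost = sum(
            costs.cost(assignment[m], m) * theta.theta[m] for m in range(n)
        )
        if best is None or cost < best.cost - 1e-12:
            best = PurePolicyResult(
                policy={m: assignment[m] for m in range(n)}, cost=float(cost), theta=theta
            )
    if best is None:
        raise StructuralError("no pure policy induced an ergodic chain")
    return best
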