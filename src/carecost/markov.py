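"""Stationary analysis of the effective chain and deterministic-policy cost.

The long-run (steady-state) distribution ``theta`` solves the balance
equations ``theta' X = theta'`` together with the normalisation
``sum(theta) = 1``.  Under the reset convention the chain has a single
recurrent class, so ``theta`` is unique; states outside that class are
transient and receive probability 0.

The deterministic-policy expected cost per patient per period is the
cost vector weighted by ``theta``:  ``E_det = sum_m c(m) * theta(m)``.

A seeded Monte-Carlo trajectory simulator provides an empirical check
of both quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import CostSchedule, EffectiveTransitionMatrix
from .errors import ConfigError, NonErgodicError, StructuralError

__all__ = [
    "StationaryDistribution",
    "stationary_distribution",
    "expected_cost_deterministic",
    "simulate_trajectories",
    "TrajectorySummary",
]

_BALANCE_TOL = 1e-9
_COND_WARN = 1e12


@dataclass(frozen=True)
class StationaryDistribution:
    """Long-run state probabilities ``theta`` with the balance residual."""

    theta: np.ndarray
    states: tuple[str, ...] | None = None
    residual: float | None = None

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float).copy()
        if theta.ndim != 1:
            raise StructuralError("theta must be a vector")
        if np.any(theta < -1e-12) or abs(theta.sum() - 1.0) > 1e-9:
            raise StructuralError(
                f"theta must be a probability vector; got sum {theta.sum()!r}"
            )
        np.clip(theta, 0.0, None, out=theta)
        theta.setflags(write=False)
        object.__setattr__(self, "theta", theta)
        if self.states is not None:
            object.__setattr__(self, "states", tuple(self.states))

    def __getitem__(self, m: int) -> float:
        return float(self.theta[m])

    def as_dict(self) -> dict[str, float]:
        labels = self.states or tuple(
            f"state_{i + 1}" for i in range(self.theta.size)
        )
        return {lab: float(v) for lab, v in zip(labels, self.theta)}


def _closed_classes(p: np.ndarray) -> list[np.ndarray]:
    """Strongly connected components with no outgoing edge (recurrent classes)."""
    n = p.shape[0]
    n_comp, labels = connected_components(
        csr_matrix(p > 0), directed=True, connection="strong"
    )
    closed = []
    for c in range(n_comp):
        members = np.where(labels == c)[0]
        outside = np.setdiff1d(np.arange(n), members)
        if outside.size == 0 or not np.any(p[np.ix_(members, outside)] > 0):
            closed.append(members)
    return closed


def stationary_distribution(
    x: EffectiveTransitionMatrix | np.ndarray,
    states: tuple[str, ...] | None = None,
) -> StationaryDistribution:
    """Unique stationary distribution of a row-stochastic chain.

    Solves ``theta' (X - I) = 0`` by replacing one redundant balance
    equation with the normalisation row and solving the dense linear
    system.  Raises :class:`NonErgodicError` when the chain has more
    than one closed recurrent class (the long-run occupancy would then
    depend on the starting state), naming the offending classes.
    """
    if isinstance(x, EffectiveTransitionMatrix):
        p = np.asarray(x.values, dtype=float)
        states = states or x.states
    else:
        p = np.asarray(x, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise StructuralError(f"transition matrix must be square, got {p.shape}")
    sums = p.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise StructuralError("chain rows must sum to 1 for stationary analysis")
    n = p.shape[0]
    labels = states or tuple(f"state_{i + 1}" for i in range(n))

    closed = _closed_classes(p)
    if len(closed) != 1:
        names = [[labels[i] for i in comp] for comp in closed]
        raise NonErgodicError(
            f"chain has {len(closed)} closed recurrent classes {names}; "
            "the stationary distribution is not unique"
        )

    a = p.T - np.eye(n)
    a[-1, :] = 1.0  # replace one redundant balance row with normalisation
    b = np.zeros(n)
    b[-1] = 1.0
    cond = np.linalg.cond(a)
    if cond > _COND_WARN:
        warnings.warn(
            f"stationary system condition number {cond:.3g} exceeds {_COND_WARN:g}; "
            "results may lose precision",
            RuntimeWarning,
            stacklevel=2,
        )
    theta = np.linalg.solve(a, b)
    theta = np.clip(theta, 0.0, None)
    theta /= theta.sum()
    residual = float(np.max(np.abs(theta @ p - theta)))
    if residual > _BALANCE_TOL:
        raise NonErgodicError(
            f"stationary solve left balance residual {residual:.3g} > {_BALANCE_TOL:g}"
        )
    return StationaryDistribution(theta, states=labels, residual=residual)


def expected_cost_deterministic(
    theta: StationaryDistribution | np.ndarray,
    costs: CostSchedule | np.ndarray,
) -> float:
    """Long-run average treatment cost per patient: ``sum_m c(m) theta(m)``.

    Linear and monotone in each state cost.  Raises
    :class:`ConfigError` if a state with positive probability has no
    finite cost.
    """
    t = theta.theta if isinstance(theta, StationaryDistribution) else np.asarray(theta, float)
    c = costs.state_costs if isinstance(costs, CostSchedule) else np.asarray(costs, float)
    if t.shape != c.shape:
        raise StructuralError(f"theta has {t.size} states but costs {c.size}")
    if np.any(~np.isfinite(c) & (t > 0)):
        raise ConfigError("missing state cost for a state with positive probability")
    return float(np.dot(np.where(np.isfinite(c), c, 0.0), t))


@dataclass(frozen=True)
class TrajectorySummary:
    """Empirical occupancy and cost from simulated patient trajectories."""

    occupancy: np.ndarray          # time-averaged state frequencies
    occupancy_se: np.ndarray       # standard error across patients
    mean_step_cost: float
    n_patients: int
    horizon: int


def simulate_trajectories(
    x: EffectiveTransitionMatrix | np.ndarray,
    costs: CostSchedule | np.ndarray,
    n_patients: int,
    horizon: int,
    seed: int,
) -> TrajectorySummary:
    """Monte-Carlo oracle for the stationary occupancy and expected cost.

    Simulates ``n_patients`` independent chains for ``horizon`` steps
    from a uniform initial state and reports the time-averaged state
    occupancy (with between-patient standard errors) and the mean
    per-step cost.  Identical seeds give identical output.
    """
    if n_patients < 1 or horizon < 1:
        raise StructuralError("n_patients and horizon must be >= 1")
    p = x.values if isinstance(x, EffectiveTransitionMatrix) else np.asarray(x, float)
    c = costs.state_costs if isinstance(costs, CostSchedule) else np.asarray(costs, float)
    n = p.shape[0]
    rng = np.random.default_rng(seed)
    cum = np.cumsum(p, axis=1)
    cum[:, -1] = 1.0  # guard against cumulative rounding

    current = rng.integers(0, n, size=n_patients)
    counts = np.zeros((n_patients, n), dtype=np.int64)
    for _ in range(horizon):
        u = rng.random(n_patients)
        nxt = np.empty_like(current)
        for s in range(n):
            mask = current == s
            if mask.any():
                nxt[mask] = np.searchsorted(cum[s], u[mask], side="right")
        current = np.minimum(nxt, n - 1)
        counts[np.arange(n_patients), current] += 1

    frac = counts / horizon
    occupancy = frac.mean(axis=0)
    se = frac.std(axis=0, ddof=1) / np.sqrt(n_patients) if n_patients > 1 else np.zeros(n)
    mean_cost = float(occupancy @ c)
    return TrajectorySummary(occupancy, se, mean_cost, n_patients, horizon)
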