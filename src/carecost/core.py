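"""Domain types for severity-ordered disease-progression cost models.

The model lives on an ordered state space of condition severities
(least to most severe).  Progression is monotone: a patient never
improves except through the designated *reset* state — the most severe
state, from which a definitive intervention (e.g. a pacemaker) returns
the patient to the least severe state with probability 1.

Three probability matrices drive the analysis:

* the **accuracy matrix** ``p{A(m), T(m')}`` — row = actual state,
  column = state the patient is treated as; the diagonal is the
  true-treatment probability;
* the **raw transition matrix** ``p{A(m) -> A(m')}`` — clinician-reported
  progression probabilities, upper-triangular apart from the reset row;
* the **effective transition matrix** ``x{A(m) -> A(m')}`` — the raw
  transitions reweighted by treatment accuracy and renormalised; this is
  the chain actually analysed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigError, InvalidMatrixError, StructuralError

__all__ = [
    "StateSpace",
    "DecisionSpace",
    "CostSchedule",
    "AccuracyMatrix",
    "RawTransitionMatrix",
    "EffectiveTransitionMatrix",
    "Violation",
    "validate_accuracy",
    "validate_transitions",
]

#: Tolerance on accuracy-matrix row sums.
ACCURACY_ROW_TOL = 1e-6
#: Tolerance on effective-matrix row sums (exact by construction).
EFFECTIVE_ROW_TOL = 1e-9
#: Default slack on raw-transition row sums.  Elicited rows need not sum
#: exactly to one (expert reports are aggregated, not renormalised), so
#: sums within ``1 ± slack`` are accepted with a warning; the effective
#: construction renormalises anyway.
DEFAULT_ROW_SLACK = 0.05


@dataclass(frozen=True)
class StateSpace:
    """Ordered severity states, least to most severe, with a reset state.

    Parameters
    ----------
    states
        State labels ordered from least to most severe (``M >= 2``).
    reset_state
        Index of the absorbing/reset state.  Defaults to the last
        (most severe) state, which returns to the first state with
        probability 1 under the reset convention.
    """

    states: tuple[str, ...]
    reset_state: int = -1

    def __post_init__(self) -> None:
        states = tuple(str(s) for s in self.states)
        object.__setattr__(self, "states", states)
        if len(states) < 2:
            raise StructuralError("state space needs at least two states")
        if len(set(states)) != len(states):
            raise StructuralError("state labels must be unique")
        reset = self.reset_state
        if reset < 0:
            reset += len(states)
        if not 0 <= reset < len(states):
            raise StructuralError(
                f"reset_state index {self.reset_state} outside 0..{len(states) - 1}"
            )
        object.__setattr__(self, "reset_state", reset)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, label: str) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise StructuralError(
                f"unknown state label {label!r}; states are {list(self.states)}"
            ) from None

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.states)


@dataclass(frozen=True)
class DecisionSpace:
    """Treatment decisions and their admissible (decision, state) pairs.

    ``admissible`` holds integer index pairs ``(decision, state)``.
    Every state must have at least one admissible decision (else the
    policy LP is infeasible) and every decision at least one state.
    """

    decisions: tuple[str, ...]
    admissible: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        decisions = tuple(str(d) for d in self.decisions)
        object.__setattr__(self, "decisions", decisions)
        if len(set(decisions)) != len(decisions):
            raise StructuralError("decision labels must be unique")
        pairs = frozenset((int(k), int(m)) for k, m in self.admissible)
        object.__setattr__(self, "admissible", pairs)
        if not pairs:
            raise StructuralError("admissible set is empty")
        used_decisions = {k for k, _ in pairs}
        missing = set(range(len(decisions))) - used_decisions
        if missing:
            names = [decisions[k] for k in sorted(missing)]
            raise StructuralError(f"decisions with no admissible state: {names}")

    @classmethod
    def from_mapping(
        cls,
        decisions: Sequence[str],
        mapping: Mapping[str, Iterable[str]],
        space: StateSpace,
    ) -> "DecisionSpace":
        """Build from ``{decision label: [state labels]}``."""
        decisions = tuple(decisions)
        pairs = set()
        for d_label, state_labels in mapping.items():
            if d_label not in decisions:
                raise ConfigError(f"admissible map names unknown decision {d_label!r}")
            k = decisions.index(d_label)
            for s_label in state_labels:
                pairs.add((k, space.index(s_label)))
        ds = cls(decisions, frozenset(pairs))
        ds.require_state_coverage(space)
        return ds

    @property
    def n_decisions(self) -> int:
        return len(self.decisions)

    def decisions_for_state(self, m: int) -> list[int]:
        return sorted(k for k, s in self.admissible if s == m)

    def require_state_coverage(self, space: StateSpace) -> None:
        """Every state must admit at least one decision."""
        covered = {m for _, m in self.admissible}
        missing = set(range(space.n_states)) - covered
        if missing:
            names = [space.states[m] for m in sorted(missing)]
            raise StructuralError(f"states with no admissible decision: {names}")

    def sorted_pairs(self) -> list[tuple[int, int]]:
        """Admissible pairs in (state, decision) order — the canonical
        variable ordering used by the policy LP."""
        return sorted(self.admissible, key=lambda km: (km[1], km[0]))


def _as_square(values, n: int | None, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise StructuralError(f"{what} must be square, got shape {arr.shape}")
    if n is not None and arr.shape[0] != n:
        raise StructuralError(
            f"{what} has size {arr.shape[0]}, state space has {n} states"
        )
    return arr


@dataclass(frozen=True)
class _LabelledMatrix:
    """A square matrix over the state space, rows and columns state-ordered."""

    values: np.ndarray
    states: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = _as_square(self.values, None, type(self).__name__)
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)
        if self.states is not None:
            states = tuple(self.states)
            if len(states) != arr.shape[0]:
                raise StructuralError(
                    f"{len(states)} labels for a {arr.shape[0]}x{arr.shape[0]} matrix"
                )
            object.__setattr__(self, "states", states)

    @property
    def n_states(self) -> int:
        return self.values.shape[0]

    def to_frame(self):
        """Return a labelled :class:`pandas.DataFrame` view."""
        import pandas as pd

        labels = self.states or [f"state_{i + 1}" for i in range(self.n_states)]
        return pd.DataFrame(self.values, index=list(labels), columns=list(labels))


class AccuracyMatrix(_LabelledMatrix):
    """Treatment probability matrix ``p{A(m), T(m')}``.

    Row ``m`` is the distribution of treated-as states given actual
    state ``m``; the diagonal entry is the true-treatment probability.
    Rows must sum to 1 within ``ACCURACY_ROW_TOL``.
    """


class RawTransitionMatrix(_LabelledMatrix):
    """Elicited progression matrix ``p{A(m) -> A(m')}``.

    Upper-triangular apart from the reset row (no recovery between
    non-reset states); row sums may deviate from 1 within a slack
    because expert means are aggregated, not renormalised.
    """


class EffectiveTransitionMatrix(_LabelledMatrix):
    """Misdiagnosis-weighted, renormalised chain ``x{A(m) -> A(m')}``.

    Strictly row-stochastic; the reset row is the unit vector on the
    first (least severe) state.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        arr = self.values
        if np.any(arr < -1e-15) or np.any(arr > 1 + 1e-12):
            raise InvalidMatrixError("effective matrix entries outside [0, 1]")
        sums = arr.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > EFFECTIVE_ROW_TOL)[0]
        if bad.size:
            raise InvalidMatrixError(
                f"effective matrix rows {bad.tolist()} sum to {sums[bad]!r}, not 1"
            )


@dataclass(frozen=True)
class CostSchedule:
    """Per-state treatment costs with optional per-(decision, state) overrides.

    ``state_costs[m]`` is the average cost of treating a patient whose
    condition occupies state ``m`` (currency units; unit-agnostic).
    ``pair_costs[(k, m)]`` overrides the state cost when decision ``k``
    is exercised in state ``m`` — e.g. a purely administrative charge
    for a watch-and-wait decision on a minor condition.
    """

    state_costs: np.ndarray
    pair_costs: Mapping[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        costs = np.asarray(self.state_costs, dtype=float)
        if costs.ndim != 1:
            raise ConfigError("state_costs must be a vector")
        if np.any(costs[np.isfinite(costs)] < 0):
            raise ConfigError("state costs must be nonnegative")
        costs = costs.copy()
        costs.setflags(write=False)
        object.__setattr__(self, "state_costs", costs)
        pairs = {(int(k), int(m)): float(c) for (k, m), c in self.pair_costs.items()}
        if any(c < 0 for c in pairs.values()):
            raise ConfigError("pair costs must be nonnegative")
        object.__setattr__(self, "pair_costs", pairs)

    @property
    def n_states(self) -> int:
        return self.state_costs.shape[0]

    def cost(self, decision: int, state: int) -> float:
        """Cost coefficient for decision ``decision`` in state ``state``."""
        key = (int(decision), int(state))
        if key in self.pair_costs:
            return self.pair_costs[key]
        c = float(self.state_costs[state])
        if not np.isfinite(c):
            raise ConfigError(
                f"no cost defined for decision {decision} in state {state}"
            )
        return c

    def require_admissible(self, decisions: DecisionSpace) -> None:
        extra = set(self.pair_costs) - set(decisions.admissible)
        if extra:
            raise ConfigError(f"pair costs for inadmissible pairs: {sorted(extra)}")


@dataclass(frozen=True)
class Violation:
    """One validation finding: ``severity`` is ``'error'`` or ``'warning'``."""

    kind: str
    where: str
    message: str
    severity: str = "error"

    def __str__(self) -> str:  # pragma: no cover - display only
        return f"[{self.severity}] {self.kind} at {self.where}: {self.message}"


def validate_accuracy(
    matrix: AccuracyMatrix, space: StateSpace | None = None
) -> list[Violation]:
    """Check an accuracy matrix: entries in [0, 1], rows summing to 1.

    Returns a (possibly empty) list of violations; an empty list means
    the matrix is valid.  A wrong-size matrix raises
    :class:`StructuralError` instead of being reported.
    """
    arr = _as_square(matrix.values, space.n_states if space else None, "accuracy matrix")
    report: list[Violation] = []
    labels = matrix.states or tuple(str(i + 1) for i in range(arr.shape[0]))
    for i, row in enumerate(arr):
        bad = np.where((row < 0) | (row > 1))[0]
        for j in bad:
            report.append(
                Violation(
                    "range",
                    f"({labels[i]}, {labels[j]})",
                    f"entry {row[j]:.6g} outside [0, 1]",
                )
            )
        s = row.sum()
        if abs(s - 1.0) > ACCURACY_ROW_TOL:
            report.append(
                Violation("row-sum", labels[i], f"row sums to {s:.6g}, expected 1")
            )
    return report


def validate_transitions(
    matrix: RawTransitionMatrix,
    space: StateSpace,
    slack: float = DEFAULT_ROW_SLACK,
    strict: bool = False,
) -> list[Violation]:
    """Check a raw transition matrix against monotone progression.

    Hard violations (``severity='error'``): any nonzero entry below the
    diagonal outside the reset row (a recovery transition), and any row
    sum outside ``[1 - slack, 1 + slack]``.  Row sums inside the slack
    band but not exactly 1 are reported as warnings.

    With ``strict=True`` any hard violation raises
    :class:`InvalidMatrixError`.
    """
    arr = _as_square(matrix.values, space.n_states, "transition matrix")
    labels = matrix.states or space.states
    report: list[Violation] = []
    for i, row in enumerate(arr):
        bad = np.where((row < 0) | (row > 1))[0]
        for j in bad:
            report.append(
                Violation(
                    "range",
                    f"({labels[i]}, {labels[j]})",
                    f"entry {row[j]:.6g} outside [0, 1]",
                )
            )
        if i != space.reset_state:
            back = np.where(row[:i] > 0)[0]
            for j in back:
                report.append(
                    Violation(
                        "backward-transition",
                        f"({labels[i]}, {labels[j]})",
                        f"progression cannot return to the less severe state "
                        f"{labels[j]!r} (probability {row[j]:.6g})",
                    )
                )
        s = row.sum()
        if abs(s - 1.0) > slack:
            report.append(
                Violation(
                    "row-sum",
                    labels[i],
                    f"row sums to {s:.6g}, outside [{1 - slack:.3g}, {1 + slack:.3g}]",
                )
            )
        elif abs(s - 1.0) > EFFECTIVE_ROW_TOL:
            report.append(
                Violation(
                    "row-sum",
                    labels[i],
                    f"row sums to {s:.6g}; accepted within slack {slack:g} "
                    "(the effective-matrix construction renormalises)",
                    severity="warning",
                )
            )
    if strict:
        hard = [v for v in report if v.severity == "error"]
        if hard:
            raise InvalidMatrixError(
                "invalid transition matrix:\n" + "\n".join(map(str, hard))
            )
    return report
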