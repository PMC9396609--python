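"""Misdiagnosis-weighted effective transition matrix.

The chain a cohort actually follows is not the clinician-reported
progression matrix: each transition competes with the probability that
the patient in state ``i`` is *treated as* state ``j``.  Assuming the
diagnosis/treatment process is independent of the progression process,
the effective probability of moving from ``i`` to ``j`` is the product
``accuracy[i, j] * raw[i, j]`` renormalised over the row:

    x[i, j] = accuracy[i, j] * raw[i, j] / sum_j accuracy[i, j] * raw[i, j]

The reset (most severe) state is absorbing-and-returned: its effective
row is the unit vector on the least severe state regardless of the
inputs, because the product form is 0/0 there (a severe case is never
treated as minor, yet the reset sends it to minor with probability 1).
"""

from __future__ import annotations

import numpy as np

from .core import AccuracyMatrix, EffectiveTransitionMatrix, RawTransitionMatrix, StateSpace
from .errors import DegenerateRowError, StructuralError

__all__ = ["effective_row", "compute_effective_matrix"]


def effective_row(
    accuracy_row: np.ndarray,
    transition_row: np.ndarray,
    is_reset: bool = False,
) -> np.ndarray:
    """Renormalised elementwise product of one accuracy and one transition row.

    Returns a probability vector summing to 1.  If ``is_reset`` the unit
    vector on state 1 is returned unconditionally.  A zero denominator on
    a non-reset row raises :class:`DegenerateRowError` — the state admits
    no treatment/transition combination with positive probability.

    The result is invariant to positive rescaling of ``transition_row``,
    so raw rows whose elicited sums drift from 1 need no prior fix-up.
    """
    a = np.asarray(accuracy_row, dtype=float)
    t = np.asarray(transition_row, dtype=float)
    if a.shape != t.shape or a.ndim != 1:
        raise StructuralError(
            f"row shapes differ or are not vectors: {a.shape} vs {t.shape}"
        )
    if is_reset:
        out = np.zeros_like(a)
        out[0] = 1.0
        return out
    w = a * t
    total = w.sum()
    if total <= 0.0:
        raise DegenerateRowError(
            "zero accuracy-weighted transition mass; the state cannot be "
            "renormalised (no admissible treatment/transition combination)"
        )
    return w / total


def compute_effective_matrix(
    accuracy: AccuracyMatrix,
    raw: RawTransitionMatrix,
    space: StateSpace,
) -> EffectiveTransitionMatrix:
    """Apply :func:`effective_row` state by state over the whole space.

    The reset state's row is hard-coded to ``[1, 0, ..., 0]``.  The
    result satisfies the row-stochastic invariant to 1e-9 by
    construction.
    """
    n = space.n_states
    if accuracy.n_states != n or raw.n_states != n:
        raise StructuralError(
            f"matrix sizes {accuracy.n_states}, {raw.n_states} do not match "
            f"the {n}-state space"
        )
    rows = []
    for i in range(n):
        try:
            rows.append(
                effective_row(
                    accuracy.values[i], raw.values[i], is_reset=(i == space.reset_state)
                )
            )
        except DegenerateRowError as exc:
            raise DegenerateRowError(
                f"state {space.states[i]!r}: {exc}"
            ) from None
    return EffectiveTransitionMatrix(np.vstack(rows), states=space.states)
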