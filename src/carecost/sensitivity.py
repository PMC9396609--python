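"""One-at-a-time sensitivity of the deterministic expected cost.

Each steady-state probability is varied over a multiplicative grid
(default 90%..110% in 1% steps) while two designated states are held
fixed and a fourth — the *absorber* — takes up the probability change
so the vector keeps summing to 1.  The assignment of held states and
absorber depends on the varied state, on whether the factor is below
or above 100%, and on the analysis condition:

* ``higher`` — the absorber choice that bounds the expected cost from
  above (probability mass shifts toward the costlier end);
* ``lower`` — the mirror assignment bounding it from below.

The two condition tables are mirror images across the 100% point and
are encoded as data; callers may override any scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CostSchedule
from .errors import InfeasiblePerturbationError, StructuralError
from .markov import StationaryDistribution, expected_cost_deterministic

__all__ = [
    "SensitivityScheme",
    "default_schemes",
    "perturb_theta",
    "sweep",
    "cost_ranges",
    "DEFAULT_FACTOR_GRID",
]

#: 90%..110% in 1% steps (21 points).
DEFAULT_FACTOR_GRID = tuple(np.round(np.arange(0.90, 1.101, 0.01), 10))

CONDITIONS = ("higher", "lower")
SEGMENTS = ("down", "up")  # factor <= 1 vs factor > 1


@dataclass(frozen=True)
class SensitivityScheme:
    """How one perturbation is redistributed.

    ``varied`` is scaled by the factor, the ``held`` states keep their
    probabilities, and ``absorber`` is set to one minus the rest.  The
    three groups must partition the state space.
    """

    varied: int
    held: tuple[int, ...]
    absorber: int
    condition: str = "higher"

    def __post_init__(self) -> None:
        members = {self.varied, self.absorber, *self.held}
        if len(members) != len(self.held) + 2:
            raise StructuralError("varied, held and absorber must be distinct states")
        if self.condition not in CONDITIONS:
            raise StructuralError(f"condition must be one of {CONDITIONS}")

    def check_partition(self, n_states: int) -> None:
        members = sorted({self.varied, self.absorber, *self.held})
        if members != list(range(n_states)):
            raise StructuralError(
                f"scheme states {members} do not partition 0..{n_states - 1}"
            )


# Base (higher-cost) table for the canonical 4-state space, indices
# 0=minor .. 3=severe: varied -> (held, absorber) per factor segment.
# The lower-cost table is the mirror image (segments swapped).
_HIGHER_TABLE = {
    "down": {
        0: ((1, 2), 3),
        1: ((0, 2), 3),
        2: ((0, 1), 3),
        3: ((0, 1), 2),
    },
    "up": {
        0: ((2, 3), 1),
        1: ((2, 3), 0),
        2: ((1, 3), 0),
        3: ((1, 2), 0),
    },
}


def default_schemes(condition: str) -> dict[tuple[int, str], SensitivityScheme]:
    """Built-in 4-state redistribution table.

    Keys are ``(varied state index, segment)`` with segment ``'down'``
    for factors at or below 1 and ``'up'`` above 1.
    """
    if condition not in CONDITIONS:
        raise StructuralError(f"condition must be one of {CONDITIONS}")
    table = {}
    for segment in SEGMENTS:
        src = segment if condition == "higher" else ("up" if segment == "down" else "down")
        for varied, (held, absorber) in _HIGHER_TABLE[src].items():
            table[(varied, segment)] = SensitivityScheme(
                varied=varied, held=held, absorber=absorber, condition=condition
            )
    return table


def perturb_theta(
    theta: StationaryDistribution,
    scheme: SensitivityScheme,
    factor: float,
) -> StationaryDistribution:
    """Scale one state probability and rebalance through the absorber.

    Raises :class:`InfeasiblePerturbationError` when the absorber would
    leave [0, 1].
    """
    t = np.asarray(theta.theta, dtype=float).copy()
    scheme.check_partition(t.size)
    t[scheme.varied] *= factor
    absorber_value = 1.0 - (t.sum() - t[scheme.absorber])
    if absorber_value < -1e-12 or absorber_value > 1.0 + 1e-12:
        raise InfeasiblePerturbationError(
            f"factor {factor:g} drives the absorbing probability to "
            f"{absorber_value:.6g}, outside [0, 1]"
        )
    t[scheme.absorber] = min(max(absorber_value, 0.0), 1.0)
    return StationaryDistribution(t, states=theta.states)


def sweep(
    theta: StationaryDistribution,
    costs: CostSchedule,
    factors: tuple[float, ...] = DEFAULT_FACTOR_GRID,
    conditions: tuple[str, ...] = CONDITIONS,
    schemes: dict[tuple[int, str], SensitivityScheme] | None = None,
) -> pd.DataFrame:
    """Evaluate the deterministic cost on every perturbed distribution.

    Returns a tidy frame with one row per (state, condition, factor):
    columns ``state``, ``condition``, ``factor``, ``expected_cost``,
    ``feasible`` and ``note``.  Infeasible grid points are recorded
    (``feasible=False``, cost ``NaN``), not fatal.  Custom ``schemes``
    (keyed like :func:`default_schemes`) override the built-in tables
    for every condition.
    """
    labels = theta.states or tuple(f"state_{i + 1}" for i in range(theta.theta.size))
    rows = []
    for condition in conditions:
        table = schemes if schemes is not None else default_schemes(condition)
        for varied in range(theta.theta.size):
            for factor in factors:
                segment = "up" if factor > 1.0 + 1e-12 else "down"
                scheme = table[(varied, segment)]
                try:
                    perturbed = perturb_theta(theta, scheme, float(factor))
                    cost = expected_cost_deterministic(perturbed, costs)
                    rows.append(
                        (labels[varied], condition, float(factor), cost, True, "")
                    )
                except InfeasiblePerturbationError as exc:
                    rows.append(
                        (labels[varied], condition, float(factor), np.nan, False, str(exc))
                    )
    return pd.DataFrame(
        rows,
        columns=["state", "condition", "factor", "expected_cost", "feasible", "note"],
    )


def cost_ranges(table: pd.DataFrame) -> pd.DataFrame:
    """Per-state cost spread over the sweep: max - min across feasible rows.

    The state with the widest spread is the most cost-sensitive one.
    """
    feasible = table[table["feasible"]]
    grouped = feasible.groupby(["state", "condition"])["expected_cost"]
    out = (grouped.max() - grouped.min()).rename("cost_range").reset_index()
    overall = (
        feasible.groupby("state")["expected_cost"].agg(lambda s: s.max() - s.min())
        .rename("cost_range")
        .reset_index()
        .assign(condition="overall")
    )
    return pd.concat([out, overall], ignore_index=True)[
        ["state", "condition", "cost_range"]
    ]
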