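"""Built-in cardiovascular case-study inputs.

A four-state cardiac severity scale (Minor, Moderate, Major, Severe)
with expert-elicited accuracy and progression matrices, average
treatment costs, and a five-decision admissibility map, as reported in
a published hospital case study from Eastern India.  The reported
steady-state vector and optimal occupancy basis from that study are
included as fixed reference inputs for downstream evaluation; note
they are the *published* values, which are not exactly reproducible
from the published (rounded) matrices.
"""

from __future__ import annotations

import numpy as np

from .core import (
    AccuracyMatrix,
    CostSchedule,
    DecisionSpace,
    RawTransitionMatrix,
    StateSpace,
)

__all__ = [
    "STATE_LABELS",
    "DECISION_LABELS",
    "cardiac_state_space",
    "cardiac_decision_space",
    "cardiac_accuracy",
    "cardiac_raw_transitions",
    "cardiac_state_costs",
    "cardiac_cost_schedule",
    "cardiac_randomized_costs",
    "DECISION_COSTS",
    "REPORTED_EFFECTIVE",
    "REPORTED_THETA",
    "REPORTED_OCCUPANCY",
]

STATE_LABELS = ("Minor", "Moderate", "Major", "Severe")
DECISION_LABELS = ("D1", "D2", "D3", "D4", "D5")

# Mean treatment (accuracy) probabilities: row = actual state,
# column = treated-as state.
_ACCURACY = np.array(
    [
        [0.701, 0.160, 0.097, 0.042],
        [0.071, 0.688, 0.127, 0.114],
        [0.100, 0.112, 0.757, 0.031],
        [0.000, 0.020, 0.101, 0.879],
    ]
)

# Mean elicited progression probabilities.  The Moderate row sums to
# 0.957 as reported (elicited means are not renormalised); the Severe
# row encodes the reset to Minor.
_RAW_TRANSITIONS = np.array(
    [
        [0.6, 0.25, 0.1, 0.05],
        [0.0, 0.58, 0.227, 0.15],
        [0.0, 0.0, 0.65, 0.35],
        [1.0, 0.0, 0.0, 0.0],
    ]
)

#: Reported effective matrix (3-decimal published values), for
#: cross-checks against the recomputed one.
REPORTED_EFFECTIVE = np.array(
    [
        [0.890, 0.085, 0.021, 0.004],
        [0.000, 0.897, 0.065, 0.038],
        [0.000, 0.000, 0.978, 0.022],
        [1.000, 0.000, 0.000, 0.000],
    ]
)

#: Average per-state treatment costs (USD) over the study period.
STATE_COSTS = (570.0, 1590.0, 6500.0, 13500.0)

#: Decision-level costs (USD): D1 is a watch-and-wait decision with an
#: administrative charge of about $50; D2..D5 carry the treatment cost
#: of the escalating intervention each decision represents.
DECISION_COSTS = (50.0, 570.0, 1590.0, 6500.0, 13500.0)

# Decision -> relevant states (the admissibility map of the case study;
# 11 admissible pairs in total).
_ADMISSIBLE = {
    "D1": ("Minor", "Moderate"),
    "D2": ("Minor", "Moderate", "Major"),
    "D3": ("Moderate", "Major", "Severe"),
    "D4": ("Major", "Severe"),
    "D5": ("Severe",),
}

#: Steady-state probabilities reported by the case study for the
#: deterministic policy (not the exact stationary vector of the
#: 3-decimal effective matrix, which is ~(0.188, 0.155, 0.637, 0.021)).
REPORTED_THETA = (0.171, 0.158, 0.650, 0.021)

#: Reported optimal occupancy basis of the randomized-policy LP,
#: keyed by (decision label, state label); omitted pairs are zero.
REPORTED_OCCUPANCY = {
    ("D1", "Minor"): 0.136,
    ("D2", "Moderate"): 0.215,
    ("D3", "Major"): 0.435,
    ("D4", "Major"): 0.097,
    ("D5", "Severe"): 0.117,
}


def cardiac_state_space() -> StateSpace:
    """Four severity states; Severe is the reset state."""
    return StateSpace(STATE_LABELS, reset_state=3)


def cardiac_decision_space() -> DecisionSpace:
    return DecisionSpace.from_mapping(DECISION_LABELS, _ADMISSIBLE, cardiac_state_space())


def cardiac_accuracy() -> AccuracyMatrix:
    return AccuracyMatrix(_ACCURACY, states=STATE_LABELS)


def cardiac_raw_transitions() -> RawTransitionMatrix:
    return RawTransitionMatrix(_RAW_TRANSITIONS, states=STATE_LABELS)


def cardiac_state_costs() -> np.ndarray:
    return np.array(STATE_COSTS)


def cardiac_cost_schedule() -> CostSchedule:
    """State costs only — the deterministic-policy cost schedule."""
    return CostSchedule(cardiac_state_costs())


def cardiac_randomized_costs() -> CostSchedule:
    """Decision-indexed cost schedule for the randomized-policy LP.

    Every admissible pair (k, m) is priced at the decision-level cost
    of k, so e.g. the watch-and-wait decision D1 costs $50 wherever it
    is admissible.
    """
    space = cardiac_state_space()
    decisions = cardiac_decision_space()
    pair_costs = {
        (k, m): DECISION_COSTS[k] for (k, m) in decisions.admissible
    }
    return CostSchedule(cardiac_state_costs(), pair_costs=pair_costs)


def reported_occupancy_indices() -> dict[tuple[int, int], float]:
    """:data:`REPORTED_OCCUPANCY` keyed by (decision index, state index)."""
    space = cardiac_state_space()
    decisions = cardiac_decision_space()
    return {
        (decisions.decisions.index(d), space.index(s)): v
        for (d, s), v in REPORTED_OCCUPANCY.items()
    }
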