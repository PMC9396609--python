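"""Model-bundle configuration: one schema for the whole two-stage model.

A config (YAML or JSON) declares the state space, decisions with their
admissible states, the cost schedule, paths to the accuracy and raw
transition CSVs, and options::

    states: [Minor, Moderate, Major, Severe]
    reset_state: Severe                # optional, default last
    decisions: [D1, D2, D3, D4, D5]
    admissible:
      D1: [Minor, Moderate]
      ...
    state_costs: {Minor: 570, Moderate: 1590, Major: 6500, Severe: 13500}
    pair_costs:
      - {decision: D1, state: Minor, cost: 50}
    accuracy: accuracy.csv             # path, relative to the config file
    transitions: transitions.csv
    options: {slack: 0.05, seed: 0}

Matrix paths are resolved relative to the config file.  Currency is
unit-agnostic: numbers are carried as given.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    AccuracyMatrix,
    CostSchedule,
    DecisionSpace,
    RawTransitionMatrix,
    StateSpace,
    validate_accuracy,
    validate_transitions,
)
from .errors import ConfigError, InvalidMatrixError
from .io import load_config_file, read_matrix_csv

__all__ = ["ModelBundle", "load_model_config"]

_DEFAULT_OPTIONS = {"slack": 0.05, "seed": 0, "factor_step": 0.01}


@dataclass(frozen=True)
class ModelBundle:
    """A fully validated model: spaces, costs, matrices and options."""

    space: StateSpace
    decisions: DecisionSpace
    costs: CostSchedule
    accuracy: AccuracyMatrix | None
    raw_transitions: RawTransitionMatrix | None
    options: dict = field(default_factory=dict)


def _require(cfg: dict, key: str):
    if key not in cfg:
        raise ConfigError(f"config is missing required field {key!r}")
    return cfg[key]


def load_model_config(path) -> ModelBundle:
    """Load and validate a model config file into a :class:`ModelBundle`.

    Every referenced matrix is loaded and validated (transitions in
    strict mode with the configured slack); schema violations raise
    :class:`~carecost.errors.ConfigError` with field-level messages.
    """
    path = Path(path)
    cfg = load_config_file(path)
    base = path.parent

    states = _require(cfg, "states")
    if not isinstance(states, list) or len(states) < 2:
        raise ConfigError("'states' must be a list of at least two labels")
    reset = cfg.get("reset_state", states[-1])
    if reset not in states:
        raise ConfigError(f"reset_state {reset!r} is not one of the declared states")
    space = StateSpace(tuple(states), reset_state=states.index(reset))

    decisions_labels = _require(cfg, "decisions")
    admissible = _require(cfg, "admissible")
    if not isinstance(admissible, dict):
        raise ConfigError("'admissible' must map decision labels to state lists")
    for d, sts in admissible.items():
        if d not in decisions_labels:
            raise ConfigError(f"admissible map names unknown decision {d!r}")
        for s in sts:
            if s not in states:
                raise ConfigError(
                    f"admissible map for {d!r} names unknown state label {s!r}"
                )
    decision_space = DecisionSpace.from_mapping(decisions_labels, admissible, space)

    raw_costs = _require(cfg, "state_costs")
    if not isinstance(raw_costs, dict):
        raise ConfigError("'state_costs' must map state labels to costs")
    missing = [s for s in states if s not in raw_costs]
    if missing:
        raise ConfigError(f"state_costs missing entries for states {missing}")
    state_costs = np.array([float(raw_costs[s]) for s in states])

    pair_costs = {}
    for entry in cfg.get("pair_costs", []):
        try:
            d, s, c = entry["decision"], entry["state"], float(entry["cost"])
        except (KeyError, TypeError) as exc:
            raise ConfigError(
                f"pair_costs entries need decision/state/cost fields: {entry!r}"
            ) from exc
        if d not in decisions_labels:
            raise ConfigError(f"pair_costs names unknown decision {d!r}")
        pair_costs[(decisions_labels.index(d), space.index(s))] = c
    costs = CostSchedule(state_costs, pair_costs=pair_costs)
    costs.require_admissible(decision_space)

    options = dict(_DEFAULT_OPTIONS)
    options.update(cfg.get("options", {}) or {})

    accuracy = None
    if "accuracy" in cfg:
        accuracy = read_matrix_csv(base / cfg["accuracy"], AccuracyMatrix, space=space)
        problems = [v for v in validate_accuracy(accuracy, space) if v.severity == "error"]
        if problems:
            raise InvalidMatrixError(
                "accuracy matrix invalid:\n" + "\n".join(map(str, problems))
            )
    transitions = None
    if "transitions" in cfg:
        transitions = read_matrix_csv(
            base / cfg["transitions"], RawTransitionMatrix, space=space
        )
        validate_transitions(
            transitions, space, slack=float(options["slack"]), strict=True
        )

    return ModelBundle(
        space=space,
        decisions=decision_space,
        costs=costs,
        accuracy=accuracy,
        raw_transitions=transitions,
        options=options,
    )
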