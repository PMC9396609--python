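"""File I/O: labelled CSV matrices, clinician-report CSVs, config files.

Matrices travel as CSV with a header row and an index column of state
labels.  Clinician reports travel as CSV with one row per clinician:
``clinician_id``, per-state ``freq_<state>`` columns and optional
``false_<state>`` columns.  Configs are YAML or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import AccuracyMatrix, RawTransitionMatrix, StateSpace
from .elicitation import ClinicianReport
from .errors import ConfigError, StructuralError

__all__ = [
    "read_matrix_csv",
    "write_matrix_csv",
    "read_reports_csv",
    "write_reports_csv",
    "load_config_file",
    "dump_json",
]


def read_matrix_csv(path, cls=None, space: StateSpace | None = None):
    """Read a labelled square matrix; ``cls`` picks the wrapper type."""
    frame = pd.read_csv(path, index_col=0)
    if list(frame.index) != list(frame.columns):
        raise StructuralError(
            f"{path}: row labels {list(frame.index)} differ from column labels "
            f"{list(frame.columns)}"
        )
    states = tuple(str(s) for s in frame.index)
    if space is not None and states != space.states:
        raise StructuralError(
            f"{path}: matrix labels {states} do not match state space {space.states}"
        )
    cls = cls or AccuracyMatrix
    return cls(frame.to_numpy(dtype=float), states=states)


def write_matrix_csv(matrix, path) -> None:
    matrix.to_frame().to_csv(path, float_format="%.17g")


def _state_labels(n: int, labels) -> list[str]:
    return list(labels) if labels is not None else [f"state_{i + 1}" for i in range(n)]


def write_reports_csv(reports: list[ClinicianReport], path, states=None) -> None:
    n = reports[0].n_states
    labels = _state_labels(n, states)
    rows = []
    for r in reports:
        row = {"clinician_id": r.clinician_id}
        row.update({f"freq_{lab}": v for lab, v in zip(labels, r.state_frequencies)})
        if r.false_treatment is not None:
            row.update({f"false_{lab}": v for lab, v in zip(labels, r.false_treatment)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_reports_csv(path) -> list[ClinicianReport]:
    frame = pd.read_csv(path)
    if "clinician_id" not in frame.columns:
        raise StructuralError(f"{path}: missing clinician_id column")
    freq_cols = [c for c in frame.columns if c.startswith("freq_")]
    false_cols = [c for c in frame.columns if c.startswith("false_")]
    if not freq_cols:
        raise StructuralError(f"{path}: no freq_<state> columns")
    reports = []
    for _, row in frame.iterrows():
        ft = row[false_cols].to_numpy(dtype=float) if false_cols else None
        reports.append(
            ClinicianReport(
                clinician_id=str(row["clinician_id"]),
                state_frequencies=row[freq_cols].to_numpy(dtype=float),
                false_treatment=ft,
            )
        )
    return reports


def load_config_file(path) -> dict:
    """Parse a YAML or JSON config into a plain dict."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    loaded = yaml.safe_load(text)
    if not isinstance(loaded, dict):
        raise ConfigError(f"{path}: config must be a mapping, got {type(loaded).__name__}")
    return loaded


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def dump_json(obj, path=None, **kwargs) -> str:
    """Serialise a (possibly numpy-laden) report to JSON, sorted keys."""
    text = json.dumps(obj, cls=_NumpyEncoder, indent=2, sort_keys=True, **kwargs)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
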