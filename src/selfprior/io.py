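"""Reading and writing the documented file dialects.

Trial and participant tables travel as CSV with exact headers; run
configurations and reports as JSON.  Write-then-read is the identity on the
data model; malformed headers are rejected with column-level messages.
Informational JSON Schema documents for each dialect ship in
``selfprior/schemas``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .tasks import PARTICIPANT_COLUMNS, TRIAL_COLUMNS

__all__ = [
    "read_trials",
    "write_trials",
    "read_participants",
    "write_participants",
    "read_json",
    "write_report",
    "to_jsonable",
]

_TRIAL_DTYPES = {
    "participant_id": str,
    "condition": str,
    "phase": str,
    "feedback_level": str,
    "excluded_reason": str,
}


def _check_header(actual, expected, path) -> None:
    missing = [c for c in expected if c not in actual]
    extra = [c for c in actual if c not in expected]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing column(s) {missing}")
        if extra:
            parts.append(f"unexpected column(s) {extra}")
        raise ParseError(f"{path}: {'; '.join(parts)}")


def write_trials(trials: pd.DataFrame, path) -> None:
    df = trials[TRIAL_COLUMNS].copy()
    df["excluded"] = df["excluded"].astype(bool)
    df.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype=_TRIAL_DTYPES, keep_default_na=True)
    _check_header(list(df.columns), TRIAL_COLUMNS, path)
    df["excluded"] = df["excluded"].map(
        {True: True, False: False, "True": True, "False": False}
    )
    if df["excluded"].isna().any():
        row = int(df.index[df["excluded"].isna()][0])
        raise ParseError(f"{path}: column 'excluded' has a non-boolean value at row {row}")
    df["excluded"] = df["excluded"].astype(bool)
    df["excluded_reason"] = df["excluded_reason"].fillna("")
    for col in ("block_index", "direction", "sweeps"):
        try:
            df[col] = df[col].astype(int)
        except (TypeError, ValueError) as e:
            raise ParseError(f"{path}: column {col!r} is not integer-valued ({e})")
    for col in ("target_x_px", "true_stop_x_px", "estimate_x_px",
                "reaction_time_s", "estimation_time_s"):
        df[col] = df[col].astype(float)
    return df


def write_participants(participants: pd.DataFrame, path) -> None:
    participants[PARTICIPANT_COLUMNS].to_csv(path, index=False)


def read_participants(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str})
    _check_header(list(df.columns), PARTICIPANT_COLUMNS, path)
    df["agent_prior_flat"] = df["agent_prior_flat"].astype(bool)
    return df


def read_json(path) -> dict:
    with open(path) as fh:
        try:
            return json.load(fh)
        except json.JSONDecodeError as e:
            raise ParseError(f"{path}: invalid JSON ({e})")


def to_jsonable(obj):
    """Recursively convert numpy/dataclass values into JSON-serialisable ones."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        if hasattr(obj, "to_dict"):
            return to_jsonable(obj.to_dict())
        return to_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else repr(v)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return to_jsonable(obj.tolist())
    if isinstance(obj, float) and not np.isfinite(obj):
        return repr(obj)
    return obj


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(to_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
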