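"""CSV input with validation, and report serialization.

The on-disk schema is fixed: UTF-8, comma-separated, header row, decimal
point.  Deposited data must be mapped onto these columns before import
(see the column-mapping template written by ``udsamp simulate``).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from udsamp.simulate import CONTROL_COLUMNS, RECORD_COLUMNS

__all__ = [
    "SchemaError",
    "read_trial_table",
    "read_control_table",
    "write_tables",
    "fingerprint",
]

_BINARY_RECORD_COLUMNS = ("knowledge_judgement", "test_correct",
                          "confidence_rating")


class SchemaError(ValueError):
    """Input table violates the documented schema; rows are 1-based."""


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _check_binary(df: pd.DataFrame, column: str, path) -> None:
    vals = pd.to_numeric(df[column], errors="coerce")
    bad = df.index[~vals.isin([0, 1])]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
        raise SchemaError(
            f"{path}: column {column!r} must be 0/1; bad value at file "
            f"row(s) {rows}"
        )


def read_trial_table(path, n_sampling_choices: int = 3) -> pd.DataFrame:
    """Read and validate the participant-by-object trial table.

    Checks the header, binary codings, the sampling-count range and the
    per-participant sum of sampling counts.  The optional ``learned``
    column (simulator output) is passed through when present.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = [c for c in RECORD_COLUMNS if c != "learned"]
    _require_columns(df, required, path)
    for col in _BINARY_RECORD_COLUMNS:
        _check_binary(df, col, path)
    ts = pd.to_numeric(df["times_sampled"], errors="coerce")
    bad = df.index[~ts.isin(range(0, n_sampling_choices + 1))]
    if len(bad):
        raise SchemaError(
            f"{path}: times_sampled must be an integer in "
            f"[0, {n_sampling_choices}]; bad value at file row "
            f"{int(bad[0]) + 2}"
        )
    sums = df.groupby("participant_id")["times_sampled"].sum()
    wrong = sums[sums != n_sampling_choices]
    if len(wrong):
        names = ", ".join(repr(p) for p in wrong.index[:5])
        raise SchemaError(
            f"{path}: times_sampled must sum to {n_sampling_choices} per "
            f"participant; violated by {names}"
        )
    return df


def read_control_table(path) -> pd.DataFrame:
    """Read and validate the control-judgement table."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, CONTROL_COLUMNS, path)
    _check_binary(df, "judged_known", path)
    bad = df.index[~df["item_class"].isin(["familiar", "unfamiliar"])]
    if len(bad):
        raise SchemaError(
            f"{path}: item_class must be 'familiar' or 'unfamiliar'; bad "
            f"value at file row {int(bad[0]) + 2}"
        )
    return df


def write_tables(records: pd.DataFrame, controls: pd.DataFrame,
                 out_dir) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec_path = out / "records.csv"
    ctl_path = out / "controls.csv"
    records.to_csv(rec_path, index=False)
    controls.to_csv(ctl_path, index=False)
    return rec_path, ctl_path


def fingerprint(payload: dict) -> str:
    """Stable hash of a JSON-serializable configuration payload."""
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
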