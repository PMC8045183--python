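"""Table and config I/O with row-level validation.

Score tables are CSV/TSV with header
``sample_id,lab_id,run_id,replicate_id,condition,score``; cohort tables use
``patient_id,pre_test,truth,score``.  Validation errors carry 1-based data
row numbers.  The decision policy and study designs are YAML (JSON is valid
YAML and therefore also accepted).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd
import yaml

from .domain import CohortRecord, DecisionPolicy, PreTestGroup, ScoreRecord
from .errors import ConfigError, DataError

__all__ = [
    "read_score_table",
    "write_score_table",
    "frame_to_records",
    "records_to_frame",
    "frame_to_cohort",
    "load_policy",
    "save_policy",
    "load_config",
    "write_json",
]

SCORE_KEY = ["sample_id", "lab_id", "run_id", "replicate_id", "condition"]
SCORE_SCHEMA = SCORE_KEY + ["score"]
COHORT_SCHEMA = ["patient_id", "pre_test", "truth", "score"]


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        return pd.read_csv(path, sep=sep, dtype=str)
    except Exception as exc:
        raise DataError(f"cannot read table {path}: {exc}") from exc


def read_score_table(path, schema: str = "score") -> pd.DataFrame:
    """Read and validate a score or cohort table.

    ``schema`` is ``"score"`` or ``"cohort"``.  Raises :class:`DataError`
    naming the offending column or data row on missing columns, non-numeric
    or non-finite scores, duplicate keys, or unknown labels.
    """
    df = _read_table(path)
    cols = SCORE_SCHEMA if schema == "score" else COHORT_SCHEMA
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s) {missing}")
    df = df[cols].copy()

    scores = pd.to_numeric(df["score"], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(scores.to_numpy(dtype=float)))
    if bad.size:
        raise DataError(
            f"{path}: non-numeric or non-finite score at data row {bad[0] + 1} "
            f"(value {df['score'].iloc[bad[0]]!r})"
        )
    df["score"] = scores.astype(float)

    key = SCORE_KEY if schema == "score" else ["patient_id"]
    dup = df.duplicated(subset=key)
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise DataError(
            f"{path}: duplicate key {tuple(df.loc[row, key])} at data row {row + 1}"
        )
    if schema == "cohort":
        for i, (g, t) in enumerate(zip(df["pre_test"], df["truth"])):
            if g not in ("low", "intermediate", "high"):
                raise DataError(f"{path}: unknown pre-test group {g!r} at data row {i + 1}")
            if t not in ("malignant", "benign"):
                raise DataError(f"{path}: unknown truth label {t!r} at data row {i + 1}")
    return df


def write_score_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False)


def frame_to_records(df: pd.DataFrame) -> List[ScoreRecord]:
    return [
        ScoreRecord(
            sample_id=str(r.sample_id),
            lab_id=str(r.lab_id),
            run_id=str(r.run_id),
            replicate_id=str(r.replicate_id),
            condition=str(r.condition),
            score=float(r.score),
        )
        for r in df.itertuples(index=False)
    ]


def records_to_frame(records: Sequence[ScoreRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=SCORE_SCHEMA)


def frame_to_cohort(df: pd.DataFrame) -> List[CohortRecord]:
    return [
        CohortRecord(
            patient_id=str(r.patient_id),
            pre_test=PreTestGroup.from_label(r.pre_test),
            truth=str(r.truth),
            score=float(r.score),
        )
        for r in df.itertuples(index=False)
    ]


def load_policy(path) -> DecisionPolicy:
    return DecisionPolicy.from_dict(load_config(path))


def save_policy(policy: DecisionPolicy, path) -> None:
    Path(path).write_text(yaml.safe_dump(policy.to_dict(), sort_keys=False))


def load_config(path) -> dict:
    try:
        data = yaml.safe_load(Path(path).read_text())
    except FileNotFoundError as exc:
        raise ConfigError(f"config file not found: {path}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a mapping, got {type(data).__name__}")
    return data


def sanitize_json(obj):
    """Replace NaN/inf floats with None so the output is strict JSON."""
    if isinstance(obj, dict):
        return {k: sanitize_json(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [sanitize_json(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, (np.floating, np.integer)):
        return sanitize_json(obj.item())
    return obj


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(
        json.dumps(sanitize_json(obj), indent=2, sort_keys=True, allow_nan=False) + "\n"
    )
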