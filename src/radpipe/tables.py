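"""Cohort feature tables.

A feature table is a pandas DataFrame with the metadata columns
``patient_id`` (unique), ``label`` (binary 0/1; the convention in the
bundled workflow is 1 = benign, 0 = malignant) and optional ``batch``
(categorical scanner/site id), followed by real-valued feature columns.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "META_COLUMNS",
    "feature_columns",
    "validate_table",
    "read_cohort_csv",
    "write_cohort_csv",
]

META_COLUMNS = ("patient_id", "label", "batch")


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the feature columns, in table order."""
    return [c for c in table.columns if c not in META_COLUMNS]


def validate_table(table: pd.DataFrame, require_batch: bool = False) -> None:
    """Check the feature-table contract; raise ValueError on violation."""
    for col in ("patient_id", "label"):
        if col not in table.columns:
            raise ValueError(f"table lacks required column {col!r}")
    if table["patient_id"].duplicated().any():
        dupes = table.loc[table["patient_id"].duplicated(), "patient_id"]
        raise ValueError(f"duplicate patient ids: {sorted(set(dupes))}")
    labels = set(table["label"].unique().tolist())
    if not labels <= {0, 1}:
        raise ValueError(f"labels must be binary 0/1, found {sorted(labels)}")
    if require_batch:
        if "batch" not in table.columns or table["batch"].isna().any():
            raise ValueError("table lacks a complete 'batch' column")
    feats = feature_columns(table)
    if not feats:
        raise ValueError("table has no feature columns")
    if table[feats].isna().any().any():
        bad = [c for c in feats if table[c].isna().any()]
        raise ValueError(f"missing values in feature columns: {bad}")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_table(table)
    return table


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path
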