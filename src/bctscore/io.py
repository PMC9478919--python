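"""Cohort table reading/writing with row-level schema validation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trialsim import CELL_TYPES, TIMEPOINTS

__all__ = ["CohortSchema", "read_cohort", "write_cohort"]

_COUNT_COLS = [f"count_{c}_{tp}" for c in CELL_TYPES for tp in TIMEPOINTS]
_ARMS = {"treated", "control"}
_RESPONSES = {"CR", "PR", "SD", "PD", "NE"}


@dataclass
class CohortSchema:
    """Required columns and row-validity rules of a wide cohort table.

    Units: counts 10^9/L, times months. Validation rejects rows with
    negative times, non-binary event flags, unknown arm labels, non-positive
    counts, or pfs_time > os_time; with ``require_pfs=False`` the PFS columns
    may be absent (loaded as missing).
    """

    require_pfs: bool = True
    id_cols: tuple = ("patient_id", "cohort", "arm")
    covariate_cols: tuple = ("sex", "age", "race", "ecog_ps", "metastasis", "pdl1_level")
    count_cols: tuple = tuple(_COUNT_COLS)
    outcome_cols: tuple = ("os_time", "os_event", "response")
    pfs_cols: tuple = ("pfs_time", "pfs_event")

    @property
    def required(self) -> list[str]:
        cols = list(self.id_cols + self.covariate_cols + self.count_cols + self.outcome_cols)
        if self.require_pfs:
            cols += list(self.pfs_cols)
        return cols

    def validate_row(self, row: pd.Series, has_pfs: bool) -> str | None:
        if row["arm"] not in _ARMS:
            return f"unknown arm label {row['arm']!r}"
        if not np.isfinite(row["os_time"]) or row["os_time"] < 0:
            return "negative or unparseable os_time"
        if row["os_event"] not in (0, 1):
            return "non-binary os_event"
        if has_pfs:
            if not np.isfinite(row["pfs_time"]) or row["pfs_time"] < 0:
                return "negative or unparseable pfs_time"
            if row["pfs_event"] not in (0, 1):
                return "non-binary pfs_event"
            if row["pfs_time"] > row["os_time"] + 1e-9:
                return "pfs_time exceeds os_time"
        if str(row["response"]) not in _RESPONSES:
            return f"unknown response {row['response']!r}"
        for col in _COUNT_COLS:
            v = row[col]
            if pd.notna(v) and v <= 0:
                return f"non-positive count in {col}"
        t1_cols = [f"count_{c}_T1" for c in CELL_TYPES]
        if row[t1_cols].isna().any():
            return "missing pre-treatment (T1) counts"
        return None


@dataclass
class ReadResult:
    cohort: pd.DataFrame
    rejected: list[dict] = field(default_factory=list)


def read_cohort(path, schema: CohortSchema | None = None) -> ReadResult:
    """Load and validate a delimited cohort table (comma or tab separated).

    Invalid rows are dropped, each recorded in ``rejected`` with its
    zero-based row index and a reason; the remainder loads normally.
    Raises ``ValueError`` when required columns are missing.
    """
    schema = schema or CohortSchema()
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    has_pfs = all(c in df.columns for c in schema.pfs_cols)
    if not has_pfs:
        for c in schema.pfs_cols:
            df[c] = np.nan

    for col in ("os_time", "os_event", "pfs_time", "pfs_event", "age",
                "pdl1_level", "ecog_ps", *_COUNT_COLS):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    rejected: list[dict] = []
    keep = np.ones(len(df), dtype=bool)
    for i, (_, row) in enumerate(df.iterrows()):
        reason = schema.validate_row(row, has_pfs)
        if reason is not None:
            keep[i] = False
            rejected.append({"row": i, "patient_id": str(row.get("patient_id", "")),
                             "reason": reason})
    return ReadResult(cohort=df[keep].reset_index(drop=True), rejected=rejected)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort as UTF-8 CSV (shortest round-trippable float repr,
    so write -> read reproduces records exactly)."""
    cohort.to_csv(path, index=False)
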