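"""Cohort CSV reading/writing, row validation and missing-data filtering.

The cohort file is a UTF-8 CSV with header.  Required columns:
``record_id, age_years, sex, mechanism, gcs, sbp, rr, outcome`` plus the
anatomy as either a precomputed ``iss`` column or the six AIS region
columns ``ais_head, ais_face, ais_chest, ais_abdomen, ais_extremity,
ais_external``.  Missing values are empty cells.  Rows violating range or
vocabulary constraints are rejected, never silently dropped: every
rejection is tallied with its line number and reason in the ingest report.
No imputation is ever performed; analyses requiring complete data use
:func:`filter_complete_cases`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CohortParseError
from .scores import compute_iss_table

__all__ = [
    "AIS_COLUMNS", "CORE_FIELDS", "IngestReport",
    "read_cohort", "write_cohort", "filter_complete_cases",
]

AIS_COLUMNS = ("ais_head", "ais_face", "ais_chest",
               "ais_abdomen", "ais_extremity", "ais_external")
#: Fields a record must carry for scoring and model fitting.
CORE_FIELDS = ("age_years", "mechanism", "gcs", "sbp", "rr", "iss", "outcome")

_REQUIRED = ("record_id", "age_years", "sex", "mechanism", "gcs", "sbp", "rr", "outcome")
_VOCAB = {
    "sex": {"male", "female"},
    "mechanism": {"blunt", "penetrating"},
    "outcome": {"alive", "dead"},
}
_NUMERIC = ("age_years", "gcs", "sbp", "rr", "iss") + AIS_COLUMNS


@dataclass
class IngestReport:
    """Bookkeeping for one cohort read: every row is accepted or tallied."""

    n_rows: int = 0
    n_accepted: int = 0
    n_rejected: int = 0
    rejections: list[tuple[int, str]] = field(default_factory=list)  # (line, reason)

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows, "n_accepted": self.n_accepted,
            "n_rejected": self.n_rejected,
            "rejections": [{"line": l, "reason": r} for l, r in self.rejections],
        }


def _row_problems(df: pd.DataFrame, has_ais: bool, has_iss: bool) -> pd.Series:
    """One reason string per bad row (empty string = accepted)."""
    reason = pd.Series("", index=df.index, dtype=object)

    def flag(mask, msg):
        new = mask & (reason == "")
        reason[new] = msg

    flag(df["age_years"].notna() & ((df["age_years"] < 0) | (df["age_years"] >= 18)),
         "age_years outside [0, 18)")
    for col, vocab in _VOCAB.items():
        flag(df[col].notna() & ~df[col].isin(vocab),
             f"{col} not in {sorted(vocab)}")
    flag(df["gcs"].notna() & ((df["gcs"] < 3) | (df["gcs"] > 15)),
         "gcs outside [3, 15]")
    for col in ("sbp", "rr"):
        flag(df[col].notna() & (df[col] < 0), f"{col} negative")
    if has_iss:
        flag(df["iss"].notna() & ((df["iss"] < 0) | (df["iss"] > 75)),
             "iss outside [0, 75]")
    if has_ais:
        for col in AIS_COLUMNS:
            flag(df[col].notna() & ((df[col] < 0) | (df[col] > 6)),
                 f"{col} outside [0, 6]")
        ais_ok = df[list(AIS_COLUMNS)].notna().all(axis=1) & (reason == "")
        if has_iss:
            both = ais_ok & df["iss"].notna()
            if both.any():
                derived = compute_iss_table(df.loc[both, list(AIS_COLUMNS)].to_numpy(int))
                mismatch = pd.Series(False, index=df.index)
                mismatch[both] = derived != df.loc[both, "iss"].to_numpy()
                flag(mismatch, "iss disagrees with AIS profile")
    return reason


def read_cohort(path) -> tuple[pd.DataFrame, IngestReport]:
    """Read and validate a cohort CSV; returns (accepted records, ingest report).

    Raises :class:`CohortParseError` on a malformed header or an unparsable
    cell (with its line number).  Range or vocabulary violations reject the
    row (tallied, not fatal).
    """
    try:
        raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except Exception as exc:  # pandas raises several parser error types
        raise CohortParseError(f"{path}: {exc}") from exc
    missing = [c for c in _REQUIRED if c not in raw.columns]
    if missing:
        raise CohortParseError(f"{path}: header is missing columns {missing}")
    has_ais = all(c in raw.columns for c in AIS_COLUMNS)
    has_iss = "iss" in raw.columns
    if not (has_ais or has_iss):
        raise CohortParseError(
            f"{path}: need either an 'iss' column or all six AIS columns"
        )

    df = raw.copy()
    for col in _NUMERIC:
        if col not in df.columns:
            continue
        probe = pd.to_numeric(df[col], errors="coerce")  # detection only
        bad = probe.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise CohortParseError(
                f"{path}: line {line}: cannot parse {col}={df[col][bad.idxmax()]!r}"
            )
        # convert via float() for exact (shortest-repr) round-tripping
        df[col] = df[col].map(
            lambda v: np.nan if pd.isna(v) or str(v).strip() == "" else float(v)
        )

    report = IngestReport(n_rows=len(df))
    reason = _row_problems(df, has_ais, has_iss)
    rejected = reason != ""
    report.rejections = [(int(i) + 2, r) for i, r in reason[rejected].items()]
    report.n_rejected = int(rejected.sum())
    accepted = df[~rejected].reset_index(drop=True)
    if has_ais and "iss" not in accepted.columns:
        complete = accepted[list(AIS_COLUMNS)].notna().all(axis=1)
        iss = pd.Series(np.nan, index=accepted.index)
        if complete.any():
            iss[complete] = compute_iss_table(
                accepted.loc[complete, list(AIS_COLUMNS)].to_numpy(int)
            )
        accepted["iss"] = iss
    report.n_accepted = len(accepted)
    return accepted, report


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort CSV (full float precision; empty cells for missing)."""
    cohort.to_csv(path, index=False)


def filter_complete_cases(
    cohort: pd.DataFrame, required_fields=CORE_FIELDS
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop records missing any required field; never impute.

    Returns the retained records and per-field missing tallies (a record
    missing two fields counts in both tallies but is dropped once).
    """
    unknown = [f for f in required_fields if f not in cohort.columns]
    if unknown:
        raise KeyError(f"required fields not in cohort: {unknown}")
    counts = {f: int(cohort[f].isna().sum()) for f in required_fields}
    keep = cohort[list(required_fields)].notna().all(axis=1)
    return cohort[keep].reset_index(drop=True), counts
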