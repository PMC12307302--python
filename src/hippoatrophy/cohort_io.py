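"""Cohort CSV schema: column dictionary, validated read, and write.

The pipeline consumes derived tabular measures (FreeSurfer-style
subcortical volumes exported to CSV), never image files. The column
dictionary below is the interchange contract; battery columns are
optional and follow ``test{i:02d}_{baseline|m18|m54}``.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .errors import ValidationError

#: required columns and their meaning (mm^3 for volumes, years for times)
COLUMN_DICTIONARY = {
    "subject_id": "unique subject identifier",
    "age_tp1": "age at the baseline scan, years",
    "interval": "time between the two scans, decimal years (> 0)",
    "sex": "female | male",
    "education": "lt9 | 9to12 | gt12 (formal years of training)",
    "apoe4": "carrier | noncarrier (APOE-e4 allele)",
    "amyloid": "positive | negative | empty/missing (amyloid PET read)",
    "icv": "estimated total intracranial volume, mm^3",
    "hippo_left_tp1": "left hippocampal volume at baseline, mm^3",
    "hippo_right_tp1": "right hippocampal volume at baseline, mm^3",
    "hippo_left_tp2": "left hippocampal volume at follow-up, mm^3",
    "hippo_right_tp2": "right hippocampal volume at follow-up, mm^3",
}

_CATEGORICAL = {
    "sex": {"female", "male"},
    "education": {"lt9", "9to12", "gt12"},
    "apoe4": {"carrier", "noncarrier"},
}
_POSITIVE = ["interval", "icv", "hippo_left_tp1", "hippo_right_tp1",
             "hippo_left_tp2", "hippo_right_tp2"]
_BATTERY_RE = re.compile(r"^test\d{2}_(baseline|m18|m54)$")


def has_battery(table: pd.DataFrame, n_tests: int = 14) -> bool:
    cols = [f"test{t:02d}_{a}" for t in range(1, n_tests + 1)
            for a in ("baseline", "m18", "m54")]
    return all(c in table.columns for c in cols)


def validate_cohort(table: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Validate types, ranges and categories; returns the typed table.

    Empty amyloid or battery cells mean "missing" and are legal; any other
    missing required field, out-of-range value, duplicate id or (in strict
    mode) unknown column raises :class:`ValidationError` naming the row
    and column.
    """
    missing_cols = [c for c in COLUMN_DICTIONARY if c not in table.columns]
    if missing_cols:
        raise ValidationError(f"cohort is missing required columns: {missing_cols}")
    if strict:
        unknown = [
            c for c in table.columns
            if c not in COLUMN_DICTIONARY and not _BATTERY_RE.match(c)
        ]
        if unknown:
            raise ValidationError(f"unknown columns (strict mode): {unknown}")

    out = table.copy()
    ids = out["subject_id"].astype(str)
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate subject_id values: {sorted(set(dup))}")
    out["subject_id"] = ids

    for col in ["age_tp1", "interval", "icv"] + _POSITIVE[2:]:
        try:
            out[col] = pd.to_numeric(out[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"column '{col}' is not numeric: {exc}") from None
        bad = out.index[out[col].isna()]
        if len(bad):
            raise ValidationError(
                f"missing required value in column '{col}', row(s) {list(bad)}"
            )
    for col in _POSITIVE:
        bad = out.index[out[col] <= 0]
        if len(bad):
            raise ValidationError(
                f"non-positive value in column '{col}', row(s) {list(bad)} "
                f"(subject {out.loc[bad[0], 'subject_id']})"
            )
    for col, allowed in _CATEGORICAL.items():
        vals = out[col].astype(str)
        bad = out.index[~vals.isin(allowed)]
        if len(bad):
            raise ValidationError(
                f"column '{col}' has values outside {sorted(allowed)} at "
                f"row(s) {list(bad)}"
            )
        out[col] = vals
    # amyloid: empty / 'missing' -> NaN; anything else must be a valid status
    amy = out["amyloid"].astype(object)
    norm = []
    for i, v in amy.items():
        if pd.isna(v) or str(v).strip() in ("", "missing", "nan"):
            norm.append(np.nan)
        elif str(v) in ("positive", "negative"):
            norm.append(str(v))
        else:
            raise ValidationError(
                f"column 'amyloid' has invalid value {v!r} at row {i}"
            )
    out["amyloid"] = norm
    for col in out.columns:
        if _BATTERY_RE.match(col):
            out[col] = pd.to_numeric(out[col], errors="coerce")
    return out


def read_cohort(path, strict: bool = True) -> pd.DataFrame:
    """Read and validate a cohort CSV (see :data:`COLUMN_DICTIONARY`)."""
    table = pd.read_csv(path, dtype={"subject_id": str})
    return validate_cohort(table, strict=strict)


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort CSV; missing amyloid/battery cells become empty."""
    table.to_csv(path, index=False)
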