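"""Annualized percent change (APC) of hippocampal volume.

APC = 100 * (V_tp2 - V_tp1) / (V_tp1 * interval), in percent per year;
negative values mean volume loss. APC is always computed on raw absolute
volumes, never on adjusted or z-scored ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

HEMISPHERES = ("left", "right")


def annualized_percent_change(v_tp1, v_tp2, interval):
    """Percent volume change per year between two scans.

    Accepts scalars or aligned arrays; v_tp1 and interval must be
    strictly positive.
    """
    v1 = np.asarray(v_tp1, dtype=float)
    v2 = np.asarray(v_tp2, dtype=float)
    t = np.asarray(interval, dtype=float)
    if np.any(v1 <= 0):
        raise ValidationError("v_tp1 must be strictly positive")
    if np.any(t <= 0):
        raise ValidationError("interval must be strictly positive")
    apc = (v2 - v1) / v1 / t * 100.0
    return float(apc) if apc.ndim == 0 else apc


def cohort_apc(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject APC records for both hemispheres plus a cohort summary.

    Returns ``(records, summary)``: ``records`` is long format
    (subject_id, hemisphere, v_tp1, v_tp2, interval, apc); ``summary`` has
    one row per hemisphere with mean/SD (ddof=1) of APC and of both
    timepoint volumes. Subjects with any missing volume or interval are
    reported collectively in a :class:`ValidationError`.
    """
    needed = ["interval"] + [
        f"hippo_{h}_tp{t}" for h in HEMISPHERES for t in (1, 2)
    ]
    missing_cols = [c for c in needed if c not in cohort.columns]
    if missing_cols:
        raise ValidationError(f"cohort is missing columns: {missing_cols}")
    bad = cohort.loc[cohort[needed].isna().any(axis=1), "subject_id"]
    if len(bad):
        raise ValidationError(
            "missing volume or interval for subjects: " + ", ".join(map(str, bad))
        )

    frames = []
    for hemi in HEMISPHERES:
        v1 = cohort[f"hippo_{hemi}_tp1"].to_numpy(float)
        v2 = cohort[f"hippo_{hemi}_tp2"].to_numpy(float)
        t = cohort["interval"].to_numpy(float)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": cohort["subject_id"],
                    "hemisphere": hemi,
                    "v_tp1": v1,
                    "v_tp2": v2,
                    "interval": t,
                    "apc": annualized_percent_change(v1, v2, t),
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    summary = (
        records.groupby("hemisphere", sort=True)
        .agg(
            n=("apc", "size"),
            apc_mean=("apc", "mean"),
            apc_sd=("apc", lambda s: s.std(ddof=1)),
            v_tp1_mean=("v_tp1", "mean"),
            v_tp1_sd=("v_tp1", lambda s: s.std(ddof=1)),
            v_tp2_mean=("v_tp2", "mean"),
            v_tp2_sd=("v_tp2", lambda s: s.std(ddof=1)),
        )
        .reset_index()
    )
    return records, summary
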