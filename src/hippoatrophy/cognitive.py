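"""Continuous Cognitive Score (CCS) from a standardized test battery.

Each neuropsychological test is converted to a z-score against the
*baseline* cohort mean and SD (so a follow-up z directly measures change
in baseline-SD units); tests where a lower raw score means better
performance are sign-flipped first. At each follow-up the number of tests
improving by at least ``delta`` SD and the number declining by at least
``delta`` SD are counted; CCS = improved - declined. Cognitive change over
the study is the sum of the CCS at the two follow-ups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError

ASSESSMENTS = ("baseline", "m18", "m54")
FOLLOWUPS = ("m18", "m54")


@dataclass(frozen=True)
class CCSRecord:
    """Improved/declined counts and their difference for one follow-up."""

    improved: int
    declined: int
    ccs: int
    n_tests_used: int


def battery_columns(n_tests: int, assessment: str) -> list[str]:
    return [f"test{t:02d}_{assessment}" for t in range(1, n_tests + 1)]


def standardize_battery(
    scores: pd.DataFrame,
    n_tests: int = 14,
    orientation=None,
    assessments: tuple[str, ...] = ASSESSMENTS,
) -> pd.DataFrame:
    """Standardize every test at every assessment against baseline norms.

    ``scores`` is wide format with columns ``test{i:02d}_{assessment}``.
    ``orientation`` maps each test index (1-based) to +1 (higher raw score
    is better, the default) or -1 (lower is better, e.g. a timed test);
    lower-is-better tests are flipped before standardization so +z always
    means better performance. Follow-up columns use the *baseline* mean/SD,
    never their own.
    """
    if n_tests < 1:
        raise ValidationError("n_tests must be >= 1")
    orient = {t: 1 for t in range(1, n_tests + 1)}
    if orientation is not None:
        for t, o in dict(orientation).items():
            if o not in (1, -1):
                raise ValidationError(
                    f"orientation for test {t} must be +1 or -1, got {o}"
                )
            orient[int(t)] = o
    out = {}
    for t in range(1, n_tests + 1):
        base_col = f"test{t:02d}_baseline"
        if base_col not in scores.columns:
            raise ValidationError(f"missing baseline column '{base_col}'")
        base = scores[base_col].to_numpy(float) * orient[t]
        obs = base[~np.isnan(base)]
        if obs.size < 2:
            raise ValidationError(
                f"test {t}: need >= 2 non-missing baseline scores"
            )
        mu, sd = obs.mean(), obs.std(ddof=1)
        if sd == 0:
            raise DegenerateTestError(t)
        for a in assessments:
            col = f"test{t:02d}_{a}"
            if col not in scores.columns:
                raise ValidationError(f"missing battery column '{col}'")
            out[col] = (scores[col].to_numpy(float) * orient[t] - mu) / sd
    return pd.DataFrame(out, index=scores.index)


class DegenerateTestError(DegenerateInputError):
    def __init__(self, test: int):
        super().__init__(f"test {test} has zero baseline SD; cannot standardize")
        self.test = test


def followup_ccs(z_baseline, z_followup, delta: float = 0.5) -> CCSRecord:
    """CCS for one subject at one follow-up from aligned per-test z-vectors.

    A test improves when z_followup - z_baseline >= +delta and declines when
    it is <= -delta ("at least" delta, so the thresholds are inclusive).
    Tests missing at either assessment contribute to neither count;
    ``n_tests_used`` records how many entered.
    """
    if delta <= 0:
        raise ValidationError("delta must be positive")
    zb = np.asarray(z_baseline, dtype=float)
    zf = np.asarray(z_followup, dtype=float)
    if zb.shape != zf.shape:
        raise ValidationError("baseline and follow-up z-vectors must be aligned")
    diff = zf - zb
    usable = ~np.isnan(diff)
    improved = int(np.sum(diff[usable] >= delta))
    declined = int(np.sum(diff[usable] <= -delta))
    return CCSRecord(
        improved=improved,
        declined=declined,
        ccs=improved - declined,
        n_tests_used=int(usable.sum()),
    )


def total_cognitive_change(ccs_18m, ccs_54m):
    """Sum of the two follow-up CCS values; None if either is missing."""
    if ccs_18m is None or ccs_54m is None:
        return None
    return ccs_18m + ccs_54m


def cohort_ccs(
    cohort: pd.DataFrame,
    n_tests: int = 14,
    orientation=None,
    delta: float = 0.5,
) -> pd.DataFrame:
    """Per-subject CCS at both follow-ups plus the total change.

    Returns one row per subject: improved/declined/ccs/n_tests_used for
    18 and 54 months and ``total_change`` = ccs_m18 + ccs_m54.
    """
    z = standardize_battery(cohort, n_tests=n_tests, orientation=orientation)
    rows = []
    for i in cohort.index:
        rec = {"subject_id": cohort.at[i, "subject_id"]}
        for fu in FOLLOWUPS:
            zb = z.loc[i, battery_columns(n_tests, "baseline")].to_numpy(float)
            zf = z.loc[i, battery_columns(n_tests, fu)].to_numpy(float)
            r = followup_ccs(zb, zf, delta=delta)
            rec[f"improved_{fu}"] = r.improved
            rec[f"declined_{fu}"] = r.declined
            rec[f"ccs_{fu}"] = r.ccs
            rec[f"n_tests_used_{fu}"] = r.n_tests_used
        rec["total_change"] = total_cognitive_change(rec["ccs_m18"], rec["ccs_m54"])
        rows.append(rec)
    return pd.DataFrame(rows)
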