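"""Residual-method normative adjustment of regional brain volumes.

A region-of-interest volume (ROIV) is regressed on head size (total
intracranial volume, TIV) and age; the residual resROIV = ROIV - fitted
is what remains of the volume after removing the normative age/head-size
trend, and is standardized into a z-score against the cohort. Outliers
beyond +/-3 z in either hemisphere are dropped subject-wise and the whole
procedure is re-run on the retained sample (two-pass), so that extreme
values do not distort the population mean and SD the z-scores refer to.

Two normative designs are supported:

* ``"quadratic"`` (default): ROIV = a*TIV^2 + b*age^2 + c*TIV*age + d*TIV
  + e*age + f, capturing the non-linear age effect on medial temporal
  volumes in elderly cohorts;
* ``"linear"``: ROIV = d*TIV + e*age + f.

TIV and age are centered and scaled internally before solving (TIV^2 spans
~1e12 mm^6, where raw normal equations lose all precision) and the
coefficients are back-transformed to the raw scale for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    SingularDesignError,
    UnderdeterminedError,
    ValidationError,
)

_MIN_FIT_N = 8
#: relative SVD cutoff below which the design is declared singular
_RANK_RTOL = 1e-10


@dataclass(frozen=True)
class ResidualModel:
    """Fitted normative volume model for one hemisphere.

    ``coefficients`` are (a, b, c, d, e, f) on the raw-scale design
    [TIV^2, age^2, TIV*age, TIV, age, 1]; for ``model="linear"`` the
    quadratic entries are exactly zero. ``residual_sd`` uses ddof=1.
    """

    coefficients: tuple[float, ...]
    n_fit: int
    residual_mean: float
    residual_sd: float
    model: str = "quadratic"
    hemisphere: str | None = None

    def predict(self, tiv, age) -> np.ndarray:
        a, b, c, d, e, f = self.coefficients
        tiv = np.asarray(tiv, dtype=float)
        age = np.asarray(age, dtype=float)
        return a * tiv**2 + b * age**2 + c * tiv * age + d * tiv + e * age + f

    def to_dict(self) -> dict:
        return {
            "hemisphere": self.hemisphere,
            "model": self.model,
            "coefficients": dict(zip("abcdef", self.coefficients)),
            "n_fit": self.n_fit,
            "residual_mean": self.residual_mean,
            "residual_sd": self.residual_sd,
        }


@dataclass(frozen=True)
class AdjustedZScores:
    """Per-subject, per-hemisphere adjusted z-scores with pass provenance.

    ``table`` has one row per subject: subject_id, pass1_z_left/right,
    pass2_z_left/right (NaN for excluded subjects) and an ``excluded``
    flag. ``models`` holds the pass-2 :class:`ResidualModel` per
    hemisphere (``pass1_models`` the pass-1 ones).
    """

    table: pd.DataFrame
    excluded_ids: tuple[str, ...]
    threshold: float
    models: dict = field(default_factory=dict)
    pass1_models: dict = field(default_factory=dict)

    @property
    def retained(self) -> pd.DataFrame:
        return self.table.loc[~self.table["excluded"]]


def _scaled_design(tiv: np.ndarray, age: np.ndarray, model: str) -> tuple:
    mt, st = tiv.mean(), tiv.std(ddof=0)
    ma, sa = age.mean(), age.std(ddof=0)
    if st == 0 or sa == 0:
        raise SingularDesignError(
            "TIV and age must both vary; constant "
            + ("TIV" if st == 0 else "age")
            + " makes the normative design singular"
        )
    u = (tiv - mt) / st
    v = (age - ma) / sa
    if model == "quadratic":
        X = np.column_stack([u**2, v**2, u * v, u, v, np.ones_like(u)])
    else:
        X = np.column_stack([u, v, np.ones_like(u)])
    return X, (mt, st, ma, sa)


def _unscale_coefficients(alpha: np.ndarray, scale: tuple, model: str) -> tuple:
    """Map coefficients on the centered/scaled design back to raw (a..f)."""
    mt, st, ma, sa = scale
    if model == "quadratic":
        a1, a2, a3, a4, a5, a6 = alpha
        a = a1 / st**2
        b = a2 / sa**2
        c = a3 / (st * sa)
        d = a4 / st - 2 * a1 * mt / st**2 - a3 * ma / (st * sa)
        e = a5 / sa - 2 * a2 * ma / sa**2 - a3 * mt / (st * sa)
        f = (
            a6
            + a1 * mt**2 / st**2
            + a2 * ma**2 / sa**2
            + a3 * mt * ma / (st * sa)
            - a4 * mt / st
            - a5 * ma / sa
        )
        return (a, b, c, d, e, f)
    a4, a5, a6 = alpha
    d = a4 / st
    e = a5 / sa
    f = a6 - a4 * mt / st - a5 * ma / sa
    return (0.0, 0.0, 0.0, d, e, f)


def fit_residual_model(
    volumes, tiv, age, *, model: str = "quadratic", hemisphere: str | None = None
) -> ResidualModel:
    """Least-squares fit of the normative volume model.

    Raises :class:`UnderdeterminedError` for n < 8 and
    :class:`SingularDesignError` when the design is rank-deficient (e.g.
    constant age); no pseudo-inverse is taken silently.
    """
    y = np.asarray(volumes, dtype=float)
    tiv = np.asarray(tiv, dtype=float)
    age = np.asarray(age, dtype=float)
    if not (y.shape == tiv.shape == age.shape) or y.ndim != 1:
        raise ValidationError("volumes, tiv and age must be aligned 1-D vectors")
    if model not in ("quadratic", "linear"):
        raise ValidationError(f"unknown normative model '{model}'")
    n = y.size
    if n < _MIN_FIT_N:
        raise UnderdeterminedError(
            f"normative fit needs at least {_MIN_FIT_N} subjects, got {n}"
        )
    if np.any(y <= 0) or np.any(tiv <= 0):
        raise ValidationError("volumes and TIV must be strictly positive")

    X, scale = _scaled_design(tiv, age, model)
    # explicit rank check on the scaled design; lstsq would happily return a
    # minimum-norm solution for a singular system
    s = np.linalg.svd(X, compute_uv=False)
    if s[-1] < _RANK_RTOL * s[0]:
        raise SingularDesignError(
            "normative design is rank-deficient (collinear TIV/age terms)"
        )
    alpha, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ alpha
    resid = y - fitted
    sd = float(np.std(resid, ddof=1))
    if sd == 0:
        sd = 0.0  # noise-free fixtures: a legal degenerate model for residuals
    return ResidualModel(
        coefficients=_unscale_coefficients(alpha, scale, model),
        n_fit=int(n),
        residual_mean=float(resid.mean()),
        residual_sd=sd,
        model=model,
        hemisphere=hemisphere,
    )


def compute_residuals(model: ResidualModel, volumes, tiv, age) -> np.ndarray:
    """resROIV = ROIV - normative prediction, in mm^3."""
    y = np.asarray(volumes, dtype=float)
    return y - model.predict(tiv, age)


def standardize(values, *, ddof: int = 1) -> np.ndarray:
    """z = (x - mean) / sample SD (ddof=1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("standardize needs at least 2 values")
    sd = x.std(ddof=ddof)
    if sd == 0:
        raise DegenerateInputError("cannot standardize a constant vector (SD = 0)")
    return (x - x.mean()) / sd


def flag_outliers(z, threshold: float = 3.0) -> np.ndarray:
    """Indices with z strictly beyond +/-threshold (|z| = threshold is kept)."""
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    z = np.asarray(z, dtype=float)
    return np.flatnonzero((z > threshold) | (z < -threshold))


def _pass_zscores(cohort: pd.DataFrame, model: str) -> tuple[dict, dict]:
    zs, models = {}, {}
    for hemi in ("left", "right"):
        m = fit_residual_model(
            cohort[f"hippo_{hemi}_tp1"],
            cohort["icv"],
            cohort["age_tp1"],
            model=model,
            hemisphere=hemi,
        )
        resid = compute_residuals(
            m, cohort[f"hippo_{hemi}_tp1"], cohort["icv"], cohort["age_tp1"]
        )
        zs[hemi] = standardize(resid)
        models[hemi] = m
    return zs, models


def two_pass_adjusted_zscores(
    cohort: pd.DataFrame, threshold: float = 3.0, *, model: str = "quadratic"
) -> AdjustedZScores:
    """Age/ICV-adjusted z-scores with one round of outlier exclusion.

    Pass 1 fits the normative model per hemisphere on everyone, standardizes
    the residuals, and flags subjects beyond the threshold in either
    hemisphere. Flagged subjects are removed entirely and the fit,
    residuals and standardization are redone on the retained sample
    (pass 2), so the reference mean/SD are uncontaminated.
    """
    required = ["hippo_left_tp1", "hippo_right_tp1", "icv", "age_tp1", "subject_id"]
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise ValidationError(f"cohort is missing required columns: {missing}")

    cohort = cohort.reset_index(drop=True)
    z1, models1 = _pass_zscores(cohort, model)
    flagged = set()
    for hemi in ("left", "right"):
        flagged.update(flag_outliers(z1[hemi], threshold).tolist())
    excluded_ids = tuple(cohort.loc[sorted(flagged), "subject_id"])

    retained_mask = ~cohort.index.isin(list(flagged))
    retained = cohort.loc[retained_mask]
    if len(retained) == 0:
        raise ValidationError("all subjects excluded as outliers; nothing to refit")

    z2, models2 = _pass_zscores(retained, model)
    table = pd.DataFrame(
        {
            "subject_id": cohort["subject_id"],
            "pass1_z_left": z1["left"],
            "pass1_z_right": z1["right"],
            "pass2_z_left": np.nan,
            "pass2_z_right": np.nan,
            "excluded": ~retained_mask,
        }
    )
    table.loc[retained_mask, "pass2_z_left"] = z2["left"]
    table.loc[retained_mask, "pass2_z_right"] = z2["right"]
    return AdjustedZScores(
        table=table,
        excluded_ids=excluded_ids,
        threshold=float(threshold),
        models=models2,
        pass1_models=models1,
    )
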