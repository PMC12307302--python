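"""Synthetic longitudinal cohort generator.

Emulates a community-based healthy-aging cohort with two structural MRI
timepoints: demographics (sex, education, APOE-e4 carriage, amyloid PET
status with missing-completely-at-random gaps), an estimated intracranial
volume, left/right hippocampal volumes generated from a known normative
model plus a subject-level residual, a latent annualized percent change
(APC) correlated with that residual, and an optional 14-test
neuropsychological battery assessed at baseline, 18 and 54 months.

Every draw comes from a named sub-stream spawned off one master seed, so
adding a downstream stage never perturbs earlier draws and identical
parameters yield bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ValidationError

HEMISPHERES = ("left", "right")

#: fixed spawn keys for the named random sub-streams
_STREAMS = {
    "demographics": 0,
    "volumes": 1,
    "battery": 2,
    "missingness": 3,
    "battery_drift": 4,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Child generator for a named sub-stream of the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings; defaults are the published cohort's values.

    Volumes are mm^3, ages and intervals years, APC in percent per year.
    ``true_coefficients`` maps each hemisphere to the (a..f) vector of the
    normative volume model on the design [TIV^2, age^2, TIV*age, TIV, age, 1].
    ``rho_baseline_apc`` is the latent correlation between a subject's
    baseline volume residual and their true APC.
    """

    n_subjects: int = 182
    seed: int = 0
    age_mean: float = 73.4
    age_sd: float = 3.5
    age_range_tp1: tuple[float, float] = (68.0, 85.0)
    interval_mean: float = 4.8
    interval_sd: float = 1.0
    female_fraction: float = 0.593
    education_fractions: tuple[float, float, float] = (0.144, 0.456, 0.400)
    apoe4_fraction: float = 0.167
    amyloid_positive_fraction: float = 0.243
    amyloid_missing_fraction: float = 79 / 182
    icv_mean: float = 1_450_000.0
    icv_sd: float = 140_000.0
    true_coefficients: dict = field(
        default_factory=lambda: {
            "left": (0.0, 0.0, 0.0, 0.0012, -35.0, 4482.37),
            "right": (0.0, 0.0, 0.0, 0.0012, -35.0, 4595.93),
        }
    )
    residual_sd: float = 316.0
    apc_mean: dict = field(default_factory=lambda: {"left": -1.79, "right": -1.34})
    apc_sd: dict = field(default_factory=lambda: {"left": 1.00, "right": 0.94})
    rho_baseline_apc: float = 0.16
    measurement_noise_sd: float = 30.0
    volume_change: str = "linear"  # or "compound"
    n_tests: int = 14
    test_drift_mean: float = -0.1
    test_drift_sd: float = 0.25
    test_noise_sd: float = 0.8

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        for name in (
            "female_fraction",
            "apoe4_fraction",
            "amyloid_positive_fraction",
            "amyloid_missing_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        ef = np.asarray(self.education_fractions, dtype=float)
        if ef.shape != (3,) or (ef < 0).any():
            raise ValidationError("education_fractions must be 3 non-negative proportions")
        if abs(ef.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"education_fractions must sum to 1, got {ef.sum():.12f}"
            )
        if not -1.0 <= self.rho_baseline_apc <= 1.0:
            raise ValidationError("rho_baseline_apc must lie in [-1, 1]")
        if self.interval_mean <= 0:
            raise ValidationError("interval_mean must be positive")
        if self.age_range_tp1[0] >= self.age_range_tp1[1]:
            raise ValidationError("age_range_tp1 must be an increasing interval")
        for name in ("age_sd", "interval_sd", "icv_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.measurement_noise_sd < 0:
            raise ValidationError("measurement_noise_sd must be non-negative")
        if self.volume_change not in ("linear", "compound"):
            raise ValidationError("volume_change must be 'linear' or 'compound'")
        if self.n_tests < 1:
            raise ValidationError("n_tests must be >= 1")
        for hemi in HEMISPHERES:
            if hemi not in self.true_coefficients:
                raise ValidationError(f"true_coefficients missing hemisphere '{hemi}'")
            if len(self.true_coefficients[hemi]) != 6:
                raise ValidationError(
                    f"true_coefficients['{hemi}'] must have 6 entries (a..f)"
                )
            if hemi not in self.apc_mean or hemi not in self.apc_sd:
                raise ValidationError(f"apc_mean/apc_sd missing hemisphere '{hemi}'")
            if self.apc_sd[hemi] < 0:
                raise ValidationError(f"apc_sd['{hemi}'] must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


def normative_volume(coefficients, tiv, age) -> np.ndarray:
    """Evaluate the quadratic normative model a*TIV^2 + b*age^2 + c*TIV*age
    + d*TIV + e*age + f."""
    a, b, c, d, e, f = (float(v) for v in coefficients)
    tiv = np.asarray(tiv, dtype=float)
    age = np.asarray(age, dtype=float)
    return a * tiv**2 + b * age**2 + c * tiv * age + d * tiv + e * age + f


def _truncnorm_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter whose [lo, hi]-truncated normal has the target mean."""
    if sd == 0:
        return target_mean

    def gap(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    return optimize.brentq(gap, lo, hi, xtol=1e-10)


def simulate_cohort(params: SimulationParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort table and its aligned ground-truth table.

    Returns ``(cohort, truth)``; ``truth`` holds the latent baseline
    residual and true APC per hemisphere plus the latent cognitive drift
    used by :func:`simulate_neuropsych`, for parameter-recovery tests.
    """
    params.validate()
    n = params.n_subjects

    demo = _rng(params.seed, "demographics")
    lo, hi = params.age_range_tp1
    loc = _truncnorm_loc(params.age_mean, params.age_sd, lo, hi)
    a, b = (lo - loc) / params.age_sd, (hi - loc) / params.age_sd
    age = stats.truncnorm.rvs(a, b, loc=loc, scale=params.age_sd, size=n, random_state=demo)
    # inter-scan interval: normal truncated below at 0.5 y (a shorter gap
    # would not be a longitudinal follow-up)
    ia = (0.5 - params.interval_mean) / params.interval_sd
    interval = stats.truncnorm.rvs(
        ia, np.inf, loc=params.interval_mean, scale=params.interval_sd, size=n,
        random_state=demo,
    )
    sex = np.where(demo.random(n) < params.female_fraction, "female", "male")
    education = demo.choice(
        ["lt9", "9to12", "gt12"], size=n, p=np.asarray(params.education_fractions) /
        np.sum(params.education_fractions),
    )
    apoe4 = np.where(demo.random(n) < params.apoe4_fraction, "carrier", "noncarrier")
    amyloid = np.where(
        demo.random(n) < params.amyloid_positive_fraction, "positive", "negative"
    ).astype(object)
    icv = demo.normal(params.icv_mean, params.icv_sd, size=n)

    vols = _rng(params.seed, "volumes")
    cohort = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:04d}" for i in range(n)],
            "age_tp1": age,
            "interval": interval,
            "sex": sex,
            "education": education,
            "apoe4": apoe4,
            "amyloid": amyloid,
            "icv": icv,
        }
    )
    truth = pd.DataFrame({"subject_id": cohort["subject_id"]})

    rho = params.rho_baseline_apc
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov) if abs(rho) < 1 else None
    for hemi in HEMISPHERES:
        zz = vols.standard_normal((n, 2))
        if chol is None:  # |rho| = 1: perfectly (anti)correlated
            zz[:, 1] = np.sign(rho) * zz[:, 0]
        else:
            zz = zz @ chol.T
        residual = zz[:, 0] * params.residual_sd
        apc = params.apc_mean[hemi] + zz[:, 1] * params.apc_sd[hemi]
        latent_tp1 = normative_volume(params.true_coefficients[hemi], icv, age) + residual
        if params.volume_change == "linear":
            latent_tp2 = latent_tp1 * (1.0 + apc / 100.0 * interval)
        else:
            latent_tp2 = latent_tp1 * (1.0 + apc / 100.0) ** interval
        noise = vols.normal(0.0, params.measurement_noise_sd, size=(n, 2))
        cohort[f"hippo_{hemi}_tp1"] = latent_tp1 + noise[:, 0]
        cohort[f"hippo_{hemi}_tp2"] = latent_tp2 + noise[:, 1]
        truth[f"residual_{hemi}"] = residual
        truth[f"apc_{hemi}"] = apc

    # latent per-follow-up cognitive drift, shared across tests; drawn here so
    # the truth table is complete whether or not a battery is simulated
    drift = _rng(params.seed, "battery_drift")
    truth["drift_m18"] = drift.normal(params.test_drift_mean, params.test_drift_sd, n)
    truth["drift_m54"] = drift.normal(params.test_drift_mean, params.test_drift_sd, n)

    if params.amyloid_missing_fraction > 0:
        cohort = apply_mcar_missingness(
            cohort, "amyloid", params.amyloid_missing_fraction, seed=params.seed
        )
    return cohort, truth


def simulate_neuropsych(params: SimulationParams, cohort: pd.DataFrame) -> pd.DataFrame:
    """Add a standardized battery of ``n_tests`` scores at baseline/18m/54m.

    Baseline scores are independent unit normals per test; each follow-up
    adds a per-subject drift (shared across tests, drawn per follow-up) plus
    independent test-retest noise. The drift draws replay the same
    ``battery_drift`` stream used by :func:`simulate_cohort`, so they match
    the truth table exactly.
    """
    params.validate()
    n = len(cohort)
    if n != params.n_subjects:
        raise ValidationError(
            f"cohort has {n} rows but params.n_subjects is {params.n_subjects}"
        )
    drift_rng = _rng(params.seed, "battery_drift")
    drift = {
        "m18": drift_rng.normal(params.test_drift_mean, params.test_drift_sd, n),
        "m54": drift_rng.normal(params.test_drift_mean, params.test_drift_sd, n),
    }
    batt = _rng(params.seed, "battery")
    out = cohort.copy()
    cols = {}
    for t in range(1, params.n_tests + 1):
        base = batt.standard_normal(n)
        cols[f"test{t:02d}_baseline"] = base
        for fu in ("m18", "m54"):
            noise = batt.normal(0.0, params.test_noise_sd, n)
            cols[f"test{t:02d}_{fu}"] = base + drift[fu] + noise
    return pd.concat([out, pd.DataFrame(cols, index=out.index)], axis=1)


def apply_mcar_missingness(
    cohort: pd.DataFrame, column: str, rate: float, seed: int
) -> pd.DataFrame:
    """Blank exactly ``round(rate * n)`` cells of ``column`` uniformly at random.

    The choice of rows is independent of every other column (missing
    completely at random). Returns a copy; the input is untouched.
    """
    if column not in cohort.columns:
        raise ValidationError(f"unknown column '{column}'")
    if not 0.0 <= rate <= 1.0:
        raise ValidationError(f"rate must lie in [0, 1], got {rate}")
    n = len(cohort)
    k = int(round(rate * n))
    out = cohort.copy()
    if k == 0:
        return out
    rows = _rng(seed, "missingness").choice(n, size=k, replace=False)
    col = out[column]
    if not (col.dtype == object or pd.api.types.is_float_dtype(col)):
        out[column] = col.astype(object)
    out.iloc[rows, out.columns.get_loc(column)] = np.nan
    return out
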