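import numpy as np
import pandas as pd
import pytest

from hippoatrophy import SimulationParams, simulate_cohort, simulate_neuropsych


@pytest.fixture(scope="session")
def default_params() -> SimulationParams:
    return SimulationParams(seed=7)


@pytest.fixture(scope="session")
def cohort_and_truth(default_params):
    return simulate_cohort(default_params)


@pytest.fixture(scope="session")
def cohort(cohort_and_truth) -> pd.DataFrame:
    return cohort_and_truth[0]


@pytest.fixture(scope="session")
def battery_cohort(default_params, cohort) -> pd.DataFrame:
    return simulate_neuropsych(default_params, cohort)


def constructed_cohort(n: int = 184, residual_sd: float = 300.0,
                       outliers: dict | None = None) -> pd.DataFrame:
    """Deterministic cohort built from normal quantiles (no sampling noise).

    Baseline residuals are the n central normal quantiles (all within
    ~±2.8 SD), so the cohort has no natural outlier; ``outliers`` maps row
    index -> residual in SD units to plant extremes.
    """
    i = np.arange(n)
    from scipy.stats import norm

    tiv = 1_300_000.0 + 2000.0 * i
    age = 68.0 + 17.0 * ((i * 37) % n) / (n - 1)  # decorrelated from TIV
    resid_units = norm.ppf((i + 0.5) / n)
    # deterministic shuffle so residuals are not collinear with the design
    order = np.argsort((i * 53) % n, kind="stable")
    resid_units = resid_units[order]
    if outliers:
        for row, sds in outliers.items():
            resid_units[row] = sds
    interval = 4.0 + (i % 5) * 0.5
    rows = {
        "subject_id": [f"C{k:04d}" for k in i],
        "age_tp1": age,
        "interval": interval,
        "sex": np.where(i % 2 == 0, "female", "male"),
        "education": np.array(["lt9", "9to12", "gt12"])[i % 3],
        "apoe4": np.where(i % 6 == 0, "carrier", "noncarrier"),
        "amyloid": np.where(i % 2 == 0, "positive", "negative").astype(object),
        "icv": tiv,
    }
    for hemi, base in (("left", 3650.0), ("right", 3760.0)):
        v1 = base + 0.0011 * tiv - 34.0 * age + resid_units * residual_sd
        rows[f"hippo_{hemi}_tp1"] = v1
        rows[f"hippo_{hemi}_tp2"] = v1 * (1.0 - 0.015 * interval)
    return pd.DataFrame(rows)
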