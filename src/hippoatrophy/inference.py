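"""Statistical stage: directional correlations, covariate-adjusted
regressions of atrophy rate on baseline z-scores, CCS regressions, and
Little's chi-square test of missing-completely-at-random amyloid data.

Conventions
-----------
The headline hypothesis is directional: a *lower* baseline z predicts a
*more negative* APC, i.e. a positive association, so the one-tailed p for
the baseline-volume term is P(T >= t). Covariates keep two-tailed p-values.
Confidence intervals are always two-sided 95%. Complete-case analysis
only — including amyloid status restricts the model to the PET subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .errors import (
    DegenerateInputError,
    MCARNotApplicableError,
    SingularDesignError,
    ValidationError,
)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    df: int
    t_stat: float
    p_one_tailed: float
    hypothesized_direction: str

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "n": self.n,
            "df": self.df,
            "t": self.t_stat,
            "p_one_tailed": self.p_one_tailed,
            "direction": self.hypothesized_direction,
        }


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit with per-term tail handling.

    ``terms`` has one row per term: term, coef, se, t, p, tail
    ('one_positive', 'one_negative' or 'two'), ci_low, ci_high (two-sided
    95%). Model-level statistics follow the usual OLS definitions.
    """

    terms: pd.DataFrame
    r_squared: float
    adj_r_squared: float
    f_stat: float
    f_pvalue: float
    n: int
    warnings: tuple[str, ...] = field(default=())

    def coef(self, term: str) -> float:
        return float(self.terms.set_index("term").at[term, "coef"])

    def pvalue(self, term: str) -> float:
        return float(self.terms.set_index("term").at[term, "p"])

    def to_dict(self) -> dict:
        return {
            "terms": self.terms.to_dict(orient="records"),
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "f_stat": self.f_stat,
            "f_pvalue": self.f_pvalue,
            "n": self.n,
            "warnings": list(self.warnings),
        }


@dataclass(frozen=True)
class MCARTestResult:
    chi2: float
    df: int
    p: float
    n_patterns: int

    def to_dict(self) -> dict:
        return {"chi2": self.chi2, "df": self.df, "p": self.p,
                "n_patterns": self.n_patterns}


def pearson_one_tailed(x, y, direction: str = "positive") -> CorrelationResult:
    """Pearson correlation with a directional (one-tailed) t-test.

    ``direction='positive'`` tests H1: rho > 0 (p = P(T >= t) on n-2 df);
    ``'negative'`` tests H1: rho < 0.
    """
    if direction not in ("positive", "negative"):
        raise ValidationError("direction must be 'positive' or 'negative'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be aligned 1-D vectors")
    n = x.size
    if n < 3:
        raise ValidationError("need at least 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError(
            "correlation undefined for a constant input vector"
        )
    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2
    if abs(r) == 1.0:
        t = np.inf * np.sign(r)
    else:
        t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = float(stats.t.sf(t, df) if direction == "positive" else stats.t.cdf(t, df))
    return CorrelationResult(
        r=r, n=n, df=df, t_stat=float(t), p_one_tailed=p,
        hypothesized_direction=direction,
    )


def _tailed_pvalue(t: float, p_two: float, tail: str) -> float:
    if tail == "two":
        return p_two
    # one-tailed in the hypothesized direction: p_two/2 when the observed
    # sign matches, 1 - p_two/2 when it does not
    matches = t >= 0 if tail == "one_positive" else t <= 0
    return p_two / 2.0 if matches else 1.0 - p_two / 2.0


def ols_fit(
    response, design: pd.DataFrame, tail_spec: dict | None = None,
    add_intercept: bool = True,
) -> RegressionResult:
    """Ordinary least squares with per-term tail specification.

    ``design`` is a named term matrix (no intercept column; one is added
    unless ``add_intercept=False``). ``tail_spec`` maps term names to
    'one_positive', 'one_negative' or 'two' (default 'two'). Confidence
    intervals stay two-sided 95% regardless of the tail used for p.
    """
    y = np.asarray(response, dtype=float)
    X = design.astype(float).copy()
    if add_intercept:
        X.insert(len(X.columns), "intercept", 1.0)
    if len(y) != len(X):
        raise ValidationError("response and design are not aligned")
    if len(y) <= X.shape[1]:
        raise ValidationError(
            f"need n > number of terms ({X.shape[1]}), got n = {len(y)}"
        )
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the collinear offenders: columns whose removal restores rank
        culprits = [
            c for c in X.columns
            if np.linalg.matrix_rank(X.drop(columns=c).to_numpy()) == rank
        ]
        raise SingularDesignError(
            f"rank-deficient design; collinear terms include {culprits}"
        )
    tail_spec = dict(tail_spec or {})
    for term, tail in tail_spec.items():
        if tail not in ("one_positive", "one_negative", "two"):
            raise ValidationError(f"unknown tail '{tail}' for term '{term}'")

    warns: list[str] = []
    if np.std(y) == 0:
        warns.append("constant response; R^2 reported as 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        fit = sm.OLS(y, X).fit()
        ci = fit.conf_int(alpha=0.05)
    rows = []
    for term in X.columns:
        t = float(fit.tvalues[term])
        rows.append(
            {
                "term": term,
                "coef": float(fit.params[term]),
                "se": float(fit.bse[term]),
                "t": t,
                "p": _tailed_pvalue(t, float(fit.pvalues[term]),
                                    tail_spec.get(term, "two")),
                "tail": tail_spec.get(term, "two"),
                "ci_low": float(ci.loc[term, 0]),
                "ci_high": float(ci.loc[term, 1]),
            }
        )
    rsq = float(fit.rsquared)
    if not np.isfinite(rsq):
        rsq = 0.0
    adj = float(fit.rsquared_adj)
    if not np.isfinite(adj):
        adj = 0.0
    fstat = float(fit.fvalue) if np.isfinite(fit.fvalue) else 0.0
    fp = float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else 1.0
    return RegressionResult(
        terms=pd.DataFrame(rows),
        r_squared=rsq,
        adj_r_squared=adj,
        f_stat=fstat,
        f_pvalue=fp,
        n=int(len(y)),
        warnings=tuple(warns),
    )


# covariate coding used by the regression models
_SEX = {"male": 0.0, "female": 1.0}
_APOE = {"noncarrier": 0.0, "carrier": 1.0}
_AMYLOID = {"negative": 0.0, "positive": 1.0}


def build_regression_frame(
    cohort: pd.DataFrame, zscores, apc_records: pd.DataFrame, hemisphere: str,
    *, z_pass: str = "pass2",
) -> pd.DataFrame:
    """Merge cohort covariates, baseline z and APC for one hemisphere.

    Rows are the retained (non-excluded) subjects; amyloid is numeric
    0/1 with NaN for missing.
    """
    if hemisphere not in ("left", "right"):
        raise ValidationError("hemisphere must be 'left' or 'right'")
    ztab = zscores.table if hasattr(zscores, "table") else zscores
    zcol = f"{z_pass}_z_{hemisphere}"
    if zcol not in ztab.columns:
        raise ValidationError(f"z-score table has no column '{zcol}'")
    apc_h = apc_records.loc[apc_records["hemisphere"] == hemisphere,
                            ["subject_id", "apc"]]
    df = (
        cohort.merge(ztab[["subject_id", zcol, "excluded"]], on="subject_id")
        .merge(apc_h, on="subject_id")
    )
    df = df.loc[~df["excluded"]]
    out = pd.DataFrame(
        {
            "subject_id": df["subject_id"],
            "apc": df["apc"].astype(float),
            "baseline_z": df[zcol].astype(float),
            "sex": df["sex"].map(_SEX),
            "age": df["age_tp1"].astype(float),
            "edu_9to12": (df["education"] == "9to12").astype(float),
            "edu_gt12": (df["education"] == "gt12").astype(float),
            "apoe4": df["apoe4"].map(_APOE),
            "amyloid": df["amyloid"].map(_AMYLOID),
        }
    )
    return out.reset_index(drop=True)


def apc_regression(
    cohort: pd.DataFrame, zscores, apc_records: pd.DataFrame, hemisphere: str,
    include_amyloid: bool, *, z_pass: str = "pass2",
) -> RegressionResult:
    """Multiple regression of hemisphere APC on baseline z plus covariates.

    Terms: baseline z (one-tailed, positive direction), sex, age, two
    education dummies (reference: < 9 years), APOE-e4 carriage, and
    amyloid status when ``include_amyloid``. Complete cases only, so with
    amyloid included n drops to the PET subset.
    """
    frame = build_regression_frame(
        cohort, zscores, apc_records, hemisphere, z_pass=z_pass
    )
    terms = ["baseline_z", "sex", "age", "edu_9to12", "edu_gt12", "apoe4"]
    if include_amyloid:
        terms.append("amyloid")
    frame = frame.dropna(subset=terms + ["apc"])
    if len(frame) < len(terms) + 10:
        warnings.warn(
            f"complete-case n = {len(frame)} is small for {len(terms)} terms",
            stacklevel=2,
        )
    return ols_fit(
        frame["apc"], frame[terms], tail_spec={"baseline_z": "one_positive"}
    )


def ccs_regression(total_change, baseline_z) -> RegressionResult:
    """Simple regression of total cognitive change on baseline z (two-tailed)."""
    y = np.asarray(total_change, dtype=float)
    z = np.asarray(baseline_z, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(z))
    design = pd.DataFrame({"baseline_z": z[keep]})
    res = ols_fit(y[keep], design)
    for w in res.warnings:
        warnings.warn(w, stacklevel=2)
    return res


# ---------------------------------------------------------------------------
# Little's MCAR test


def _em_mvnorm(X: np.ndarray, tol: float = 1e-6, max_iter: int = 200):
    """ML mean/covariance of a multivariate normal with missing entries (EM)."""
    n, p = X.shape
    obs = ~np.isnan(X)
    mu = np.nanmean(X, axis=0)
    filled = np.where(obs, X, mu)
    sigma = np.cov(filled, rowvar=False, ddof=0)
    sigma += np.eye(p) * 1e-8 * max(np.trace(sigma) / p, 1.0)

    patterns: dict[tuple, np.ndarray] = {}
    for i in range(n):
        patterns.setdefault(tuple(obs[i]), []).append(i)
    patterns = {k: np.asarray(v) for k, v in patterns.items()}

    for _ in range(max_iter):
        s1 = np.zeros(p)
        s2 = np.zeros((p, p))
        for pat, idx in patterns.items():
            o = np.asarray(pat)
            m = ~o
            Xo = X[np.ix_(idx, o)]
            if m.any():
                Soo = sigma[np.ix_(o, o)]
                Smo = sigma[np.ix_(m, o)]
                reg = np.linalg.solve(Soo, Smo.T).T
                Xm = mu[m] + (Xo - mu[o]) @ reg.T
                condv = sigma[np.ix_(m, m)] - reg @ Smo.T
            full = np.empty((len(idx), p))
            full[:, o] = Xo
            if m.any():
                full[:, m] = Xm
            s1 += full.sum(axis=0)
            s2 += full.T @ full
            if m.any():
                cc = np.zeros((p, p))
                cc[np.ix_(m, m)] = condv * len(idx)
                s2 += cc
        mu_new = s1 / n
        sigma_new = s2 / n - np.outer(mu_new, mu_new)
        shift = max(
            np.max(np.abs(mu_new - mu)),
            np.max(np.abs(sigma_new - sigma)),
        )
        scale = max(1.0, np.max(np.abs(sigma)))
        mu, sigma = mu_new, sigma_new
        if shift < tol * scale:
            break
    return mu, sigma, patterns


def little_mcar_test(
    data: pd.DataFrame, missing_column: str | None = None
) -> MCARTestResult:
    """Little's (1988) chi-square test that data are MCAR.

    ``data`` holds quantitative variables with missing cells. The grand
    mean and covariance are estimated by EM under the multivariate-normal
    model; the statistic sums, over missingness patterns j,
    n_j * (xbar_j - mu_obs)' Sigma_obs^-1 (xbar_j - mu_obs) restricted to
    the variables observed in that pattern, on sum_j p_j - p degrees of
    freedom. A large value means pattern means differ more than chance,
    i.e. evidence against MCAR.

    If ``missing_column`` is given, rows missing any *other* variable are
    dropped first, so the test targets that column's missingness.
    """
    df = data.copy()
    num = df.select_dtypes(include=[np.number])
    if num.shape[1] < df.shape[1]:
        raise ValidationError(
            "little_mcar_test expects quantitative variables only; "
            f"non-numeric columns: {sorted(set(df.columns) - set(num.columns))}"
        )
    if missing_column is not None:
        if missing_column not in df.columns:
            raise ValidationError(f"unknown column '{missing_column}'")
        others = [c for c in df.columns if c != missing_column]
        df = df.dropna(subset=others)
    X = df.to_numpy(float)
    X = X[~np.isnan(X).all(axis=1)]
    n, p = X.shape
    if p < 2:
        raise ValidationError("need at least 2 quantitative variables")
    if not np.isnan(X).any():
        raise MCARNotApplicableError(
            "no missing cells: a single missingness pattern, MCAR test "
            "not applicable"
        )
    mu, sigma, patterns = _em_mvnorm(X)
    if len(patterns) < 2:
        raise MCARNotApplicableError(
            "only one missingness pattern present; MCAR test not applicable"
        )
    chi2 = 0.0
    df_total = 0
    for pat, idx in patterns.items():
        o = np.asarray(pat)
        xbar = X[np.ix_(idx, o)].mean(axis=0)
        d = xbar - mu[o]
        Soo = sigma[np.ix_(o, o)]
        chi2 += len(idx) * float(d @ np.linalg.solve(Soo, d))
        df_total += int(o.sum())
    dof = df_total - p
    pval = float(stats.chi2.sf(chi2, dof)) if dof > 0 else float("nan")
    return MCARTestResult(chi2=float(chi2), df=int(dof), p=pval,
                          n_patterns=len(patterns))
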