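"""Directional correlation, OLS with per-term tails, the covariate
regressions, and Little's MCAR test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hippoatrophy import (
    DegenerateInputError,
    MCARNotApplicableError,
    SimulationParams,
    SingularDesignError,
    ValidationError,
    apc_regression,
    ccs_regression,
    cohort_apc,
    little_mcar_test,
    ols_fit,
    pearson_one_tailed,
    simulate_cohort,
    two_pass_adjusted_zscores,
)


class TestPearsonOneTailed:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        res = pearson_one_tailed(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.p_one_tailed == pytest.approx(0.0, abs=1e-12)

    def test_hand_fixture(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        res = pearson_one_tailed(x, y)
        # Sxy = 10, Sxx = 10, Syy = 14.8 by hand
        assert res.r == pytest.approx(10 / np.sqrt(10 * 14.8), abs=1e-12)
        assert res.df == 3
        t = res.r * np.sqrt(3) / np.sqrt(1 - res.r**2)
        assert res.p_one_tailed == pytest.approx(stats.t.sf(t, 3), abs=1e-12)
        assert res.p_one_tailed == pytest.approx(0.044, abs=5e-4)

    def test_matches_scipy(self):
        rng = np.random.default_rng(17)
        x, y = rng.normal(size=(2, 40))
        res = pearson_one_tailed(x, y, direction="positive")
        ref = stats.pearsonr(x, y, alternative="greater")
        assert res.r == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_one_tailed == pytest.approx(ref.pvalue, abs=1e-12)

    def test_wrong_direction_extreme(self):
        x = np.arange(10.0)
        res = pearson_one_tailed(x, -x, direction="positive")
        assert res.r == pytest.approx(-1.0)
        assert res.p_one_tailed == pytest.approx(1.0)

    def test_opposite_directions_complement(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(2, 25))
        pos = pearson_one_tailed(x, y, "positive").p_one_tailed
        neg = pearson_one_tailed(x, y, "negative").p_one_tailed
        assert pos + neg == pytest.approx(1.0, abs=1e-12)

    def test_constant_input_errors(self):
        with pytest.raises(DegenerateInputError):
            pearson_one_tailed([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def ols_oracle(X: np.ndarray, y: np.ndarray):
    """Brute-force OLS: normal equations + classical t/F statistics."""
    n, p = X.shape
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    s2 = resid @ resid / (n - p)
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p_two = 2 * stats.t.sf(np.abs(t), n - p)
    tcrit = stats.t.ppf(0.975, n - p)
    ybar = y.mean()
    ss_tot = ((y - ybar) ** 2).sum()
    ss_res = (resid**2).sum()
    r2 = 1 - ss_res / ss_tot
    k = p - 1  # slopes, excluding intercept
    f = (ss_tot - ss_res) / k / s2
    fp = stats.f.sf(f, k, n - p)
    return dict(beta=beta, se=se, t=t, p_two=p_two,
                ci=(beta - tcrit * se, beta + tcrit * se), r2=r2,
                adj=1 - (1 - r2) * (n - 1) / (n - p), f=f, fp=fp)


class TestOLS:
    def test_noise_free_slope(self):
        z = np.linspace(-2, 2, 20)
        res = ols_fit(0.16 * z, pd.DataFrame({"z": z}))
        assert res.coef("z") == pytest.approx(0.16, abs=1e-12)
        assert res.coef("intercept") == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)

    def test_twelve_row_fixture_matches_oracle(self):
        rng = np.random.default_rng(11)
        design = pd.DataFrame(
            {"a": rng.normal(size=12), "b": rng.normal(size=12)}
        )
        y = 1.5 * design["a"] - 0.5 * design["b"] + rng.normal(0, 0.8, 12)
        res = ols_fit(y, design)
        X = np.column_stack([design["a"], design["b"], np.ones(12)])
        ref = ols_oracle(X, y.to_numpy())
        terms = res.terms.set_index("term").loc[["a", "b", "intercept"]]
        np.testing.assert_allclose(terms["coef"], ref["beta"], rtol=1e-8)
        np.testing.assert_allclose(terms["se"], ref["se"], rtol=1e-8)
        np.testing.assert_allclose(terms["t"], ref["t"], rtol=1e-8)
        np.testing.assert_allclose(terms["p"], ref["p_two"], rtol=1e-8)
        np.testing.assert_allclose(terms["ci_low"], ref["ci"][0], rtol=1e-8)
        np.testing.assert_allclose(terms["ci_high"], ref["ci"][1], rtol=1e-8)
        assert res.r_squared == pytest.approx(ref["r2"], rel=1e-10)
        assert res.adj_r_squared == pytest.approx(ref["adj"], rel=1e-10)
        assert res.f_stat == pytest.approx(ref["f"], rel=1e-10)
        assert res.f_pvalue == pytest.approx(ref["fp"], rel=1e-10)

    def test_one_tailed_is_half_two_tailed_when_sign_matches(self):
        rng = np.random.default_rng(2)
        design = pd.DataFrame({"x": rng.normal(size=30)})
        y = 0.5 * design["x"] + rng.normal(0, 1, 30)
        two = ols_fit(y, design)
        one = ols_fit(y, design, tail_spec={"x": "one_positive"})
        trow = two.terms.set_index("term").loc["x"]
        orow = one.terms.set_index("term").loc["x"]
        assert trow["t"] > 0
        assert orow["p"] == pytest.approx(trow["p"] / 2, abs=1e-15)
        # wrong direction: complement
        neg = ols_fit(y, design, tail_spec={"x": "one_negative"})
        nrow = neg.terms.set_index("term").loc["x"]
        assert nrow["p"] == pytest.approx(1 - trow["p"] / 2, abs=1e-15)

    def test_ci_coverage_simulation(self):
        rng = np.random.default_rng(101)
        true = {"x1": 0.8, "x2": -0.3}
        hits = 0
        reps = 1000
        for _ in range(reps):
            design = pd.DataFrame({"x1": rng.normal(size=30),
                                   "x2": rng.normal(size=30)})
            y = (true["x1"] * design["x1"] + true["x2"] * design["x2"]
                 + rng.normal(0, 1, 30))
            res = ols_fit(y, design)
            row = res.terms.set_index("term").loc["x1"]
            hits += row["ci_low"] <= true["x1"] <= row["ci_high"]
        assert hits / reps == pytest.approx(0.95, abs=0.02)

    def test_collinear_terms_named(self):
        x = np.arange(12.0)
        design = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.raises(SingularDesignError, match="x"):
            ols_fit(np.arange(12.0), design)

    def test_n_must_exceed_terms(self):
        with pytest.raises(ValidationError):
            ols_fit([1.0, 2.0], pd.DataFrame({"a": [1.0, 2.0],
                                              "b": [3.0, 1.0]}))


@pytest.fixture(scope="module")
def analysis_inputs():
    cohort, _ = simulate_cohort(SimulationParams(seed=31))
    zs = two_pass_adjusted_zscores(cohort)
    retained = cohort[~cohort["subject_id"].isin(zs.excluded_ids)].reset_index(
        drop=True)
    records, _ = cohort_apc(retained)
    return retained, zs, records


class TestAPCRegression:
    def test_complete_case_n_drops_with_amyloid(self, analysis_inputs):
        retained, zs, records = analysis_inputs
        full = apc_regression(retained, zs, records, "right",
                              include_amyloid=False)
        sub = apc_regression(retained, zs, records, "right",
                             include_amyloid=True)
        n_pet = int(retained["amyloid"].notna().sum())
        assert full.n == len(retained)
        assert sub.n == n_pet
        assert "amyloid" in sub.terms["term"].tolist()
        assert "amyloid" not in full.terms["term"].tolist()

    def test_education_reference_is_lt9(self, analysis_inputs):
        retained, zs, records = analysis_inputs
        res = apc_regression(retained, zs, records, "left",
                             include_amyloid=False)
        terms = res.terms["term"].tolist()
        assert "edu_9to12" in terms and "edu_gt12" in terms
        assert not any(t.startswith("edu_lt9") for t in terms)

    def test_baseline_z_is_one_tailed(self, analysis_inputs):
        retained, zs, records = analysis_inputs
        res = apc_regression(retained, zs, records, "left",
                             include_amyloid=False)
        row = res.terms.set_index("term").loc["baseline_z"]
        assert row["tail"] == "one_positive"

    def test_permutation_invariance(self, analysis_inputs):
        retained, zs, records = analysis_inputs
        res = apc_regression(retained, zs, records, "right",
                             include_amyloid=False)
        perm = retained.sample(frac=1.0, random_state=5).reset_index(drop=True)
        res2 = apc_regression(perm, zs, records, "right",
                              include_amyloid=False)
        pd.testing.assert_frame_equal(
            res.terms, res2.terms, check_exact=False, atol=1e-12
        )
        assert res.n == res2.n

    def test_slope_recovery(self):
        # generator couples residual and APC only; covariate effects are 0
        p = SimulationParams(
            n_subjects=2000, seed=77, rho_baseline_apc=0.15,
            apc_sd={"left": 1.0, "right": 1.0}, measurement_noise_sd=0.0,
        )
        cohort, _ = simulate_cohort(p)
        zs = two_pass_adjusted_zscores(cohort)
        retained = cohort[~cohort["subject_id"].isin(zs.excluded_ids)]
        retained = retained.reset_index(drop=True)
        records, _ = cohort_apc(retained)
        res = apc_regression(retained, zs, records, "left",
                             include_amyloid=False)
        assert res.coef("baseline_z") == pytest.approx(0.15, abs=0.07)


class TestCCSRegression:
    def test_noise_free_slope(self):
        z = np.linspace(-2, 2, 15)
        res = ccs_regression(2.0 * z, z)
        assert res.coef("baseline_z") == pytest.approx(2.0, abs=1e-12)

    def test_constant_response_degenerates_gracefully(self):
        z = np.linspace(-2, 2, 15)
        with pytest.warns(UserWarning, match="constant response"):
            res = ccs_regression(np.zeros(15), z)
        assert res.coef("baseline_z") == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == 0.0

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(55)
        reps, n, rejections = 1000, 40, 0
        for _ in range(reps):
            z = rng.normal(size=n)
            ccs = rng.normal(size=n)  # independent of z: slope truly 0
            res = ccs_regression(ccs, z)
            rejections += res.pvalue("baseline_z") < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.015)


class TestLittleMCAR:
    def test_no_missing_not_applicable(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(50, 3)),
                          columns=list("abc"))
        with pytest.raises(MCARNotApplicableError):
            little_mcar_test(df)

    def test_mcar_data_large_p(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(400, 3)), columns=list("abc"))
        df.loc[rng.choice(400, 120, replace=False), "c"] = np.nan
        res = little_mcar_test(df)
        assert res.n_patterns == 2
        assert res.df == 2
        assert res.p > 0.01  # no systematic pattern difference

    def test_mar_mechanism_detected(self):
        rng = np.random.default_rng(9)
        n = 500
        x = rng.normal(size=n)
        y = 0.8 * x + rng.normal(0, 0.6, n)
        z = rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        # y goes missing mostly when x is high -> observed-y mean shifts
        miss = rng.random(n) < np.where(x > 0, 0.7, 0.05)
        df.loc[miss, "y"] = np.nan
        res = little_mcar_test(df)
        assert res.p < 0.001

    def test_non_numeric_rejected(self):
        df = pd.DataFrame({"a": [1.0, np.nan], "b": ["x", "y"]})
        with pytest.raises(ValidationError, match="b"):
            little_mcar_test(df)

    def test_missing_column_focus(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.normal(size=(300, 3)), columns=list("abc"))
        df.loc[rng.choice(300, 90, replace=False), "c"] = np.nan
        df.loc[rng.choice(300, 10, replace=False), "a"] = np.nan
        res = little_mcar_test(df, missing_column="c")
        assert res.n_patterns == 2
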