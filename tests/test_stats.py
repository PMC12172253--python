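"""Statistical engine: Spearman, standardization, OLS, LASSO, CV, power."""

import numpy as np
import pandas as pd
import pytest

from interopipe import (
    PowerSpec,
    cross_validate,
    fit_lasso_cv,
    fit_ols,
    power_regression,
    spearman_matrix,
    standardize,
)
from interopipe.exceptions import (
    AliasingError,
    InvalidParameterError,
    UndefinedStatisticError,
)
from interopipe.stats import default_lambda_grid, lambda_max, regression_power


def _xy_table(n=60, p=3, beta=None, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.arange(1, p + 1, dtype=float) if beta is None else np.asarray(beta)
    y = X @ beta + noise * rng.normal(size=n)
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
    df["y"] = y
    return df, [f"x{i}" for i in range(p)]


class TestSpearman:
    def test_monotone_relationships(self):
        df = pd.DataFrame({"a": np.arange(20.0), "b": np.exp(np.arange(20.0) / 5)})
        df["c"] = -df["b"]
        mat = spearman_matrix(df)
        assert mat.rho.loc["a", "b"] == pytest.approx(1.0)
        assert mat.rho.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(mat.rho.to_numpy(), mat.rho.to_numpy().T)

    def test_independent_null(self, rng):
        df = pd.DataFrame(rng.normal(size=(10_000, 2)), columns=["a", "b"])
        assert abs(spearman_matrix(df).rho.loc["a", "b"]) < 0.03

    def test_constant_variable_undefined(self):
        df = pd.DataFrame({"a": np.arange(10.0), "b": np.ones(10)})
        assert np.isnan(spearman_matrix(df).rho.loc["a", "b"])

    def test_pairwise_deletion_counts(self):
        df = pd.DataFrame({"a": np.arange(10.0), "b": np.arange(10.0)})
        df.loc[:2, "b"] = np.nan
        mat = spearman_matrix(df)
        assert mat.n.loc["a", "b"] == 7


class TestStandardize:
    def test_moments(self, rng):
        df = pd.DataFrame(rng.normal(3, 5, size=(40, 2)), columns=["a", "b"])
        out = standardize(df)
        assert np.allclose(out.mean(), 0, atol=1e-12)
        assert np.allclose(out.std(ddof=1), 1, atol=1e-12)

    def test_idempotence(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        once = standardize(df)
        twice = standardize(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_small_example(self):
        out = standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(out["a"], [-1.0, 0.0, 1.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            standardize(pd.DataFrame({"a": [2.0, 2.0, 2.0]}))


class TestOLS:
    def test_exact_linear_outcome(self):
        df, preds = _xy_table(noise=0.0)
        res = fit_ols(df, "y", preds)
        assert res.rsquared == pytest.approx(1.0)
        np.testing.assert_allclose(res.params[preds], [1, 2, 3], atol=1e-8)
        assert np.all(res.bse[preds] < 1e-6)

    def test_matches_normal_equations(self, rng):
        # explicit (X'X)^{-1} X'y on a small instance
        df, preds = _xy_table(n=15, p=3, noise=0.7, seed=4)
        res = fit_ols(df, "y", preds)
        X = np.hstack([np.ones((15, 1)), df[preds].to_numpy()])
        beta = np.linalg.inv(X.T @ X) @ X.T @ df["y"].to_numpy()
        np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-10)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        df, preds = _xy_table(n=40, p=4, noise=1.0, seed=5)
        res = fit_ols(df, "y", preds)
        ref = sm.OLS(df["y"], sm.add_constant(df[preds])).fit()
        np.testing.assert_allclose(res.params[preds], ref.params[preds], atol=1e-10)
        np.testing.assert_allclose(res.bse[preds], ref.bse[preds], atol=1e-10)
        np.testing.assert_allclose(res.pvalues[preds], ref.pvalues[preds], atol=1e-10)
        assert res.fvalue == pytest.approx(ref.fvalue)
        assert res.df_num == ref.df_model and res.df_den == ref.df_resid

    def test_t_equals_beta_over_se(self):
        df, preds = _xy_table(n=50, noise=0.5, seed=6)
        res = fit_ols(df, "y", preds)
        np.testing.assert_allclose(
            res.tvalues.to_numpy(), (res.params / res.bse).to_numpy()
        )

    def test_rank_deficiency_names_columns(self):
        df, preds = _xy_table(n=30, noise=0.5, seed=7)
        df["x_dup"] = df["x0"]
        with pytest.raises(AliasingError) as exc:
            fit_ols(df, "y", preds + ["x_dup"])
        assert {"x0", "x_dup"} <= set(exc.value.columns)


class TestLasso:
    def test_all_zero_at_lambda_max(self):
        df, preds = _xy_table(n=80, noise=0.5, seed=8)
        lmax = lambda_max(df, "y", preds)
        res = fit_lasso_cv(df, "y", preds, lambda_grid=np.array([2 * lmax, 1.5 * lmax, lmax * 1.0001]))
        assert res.nonzero == 0

    def test_unpenalized_limit_matches_ols(self):
        df, preds = _xy_table(n=120, noise=0.3, seed=9)
        ols = fit_ols(df, "y", preds)
        lmax = lambda_max(df, "y", preds)
        grid = np.geomspace(lmax, lmax * 1e-8, 60)
        res = fit_lasso_cv(df, "y", preds, lambda_grid=grid, seed=1)
        # refit at the smallest grid penalty: effectively unpenalized
        from interopipe.stats import _fit_lasso

        tiny = _fit_lasso(df[preds].to_numpy(), df["y"].to_numpy(), grid[-1])
        np.testing.assert_allclose(tiny.coef_, ols.params[preds], atol=1e-4)

    def test_soft_threshold_oracle_orthonormal_design(self):
        # for X with X'X/n = I the solution is soft(X'y/n, lambda)
        rng = np.random.default_rng(10)
        n, p = 200, 5
        a = np.hstack([np.ones((n, 1)), rng.normal(size=(n, p))])
        q, _ = np.linalg.qr(a)
        X = q[:, 1:] * np.sqrt(n)  # columns: mean 0, X'X/n = I
        beta = np.array([1.0, -0.5, 0.25, 0.0, 0.0])
        y = X @ beta + 0.1 * rng.normal(size=n)
        lam = 0.2
        from interopipe.stats import _fit_lasso

        fit = _fit_lasso(X, y, lam)
        b = X.T @ (y - y.mean()) / n
        expected = np.sign(b) * np.maximum(np.abs(b) - lam, 0.0)
        np.testing.assert_allclose(fit.coef_, expected, atol=1e-6)

    def test_l1_norm_decreases_along_penalty(self):
        df, preds = _xy_table(n=100, noise=0.5, seed=11)
        from interopipe.stats import _fit_lasso

        X, y = df[preds].to_numpy(), df["y"].to_numpy()
        grid = default_lambda_grid(lambda_max(df, "y", preds), n_points=20)
        norms = [np.abs(_fit_lasso(X, y, lam).coef_).sum() for lam in grid]
        assert np.all(np.diff(norms) >= -1e-8)  # grid descends, norms grow

    def test_grid_extension_warns(self):
        df, preds = _xy_table(n=60, noise=0.5, seed=12)
        lmax = lambda_max(df, "y", preds)
        with pytest.warns(UserWarning, match="lambda_max"):
            fit_lasso_cv(df, "y", preds, lambda_grid=np.geomspace(lmax / 10, lmax / 100, 10))

    def test_seed_reproducibility(self):
        df, preds = _xy_table(n=90, noise=1.0, seed=13)
        a = fit_lasso_cv(df, "y", preds, seed=3)
        b = fit_lasso_cv(df, "y", preds, seed=3)
        assert a.lambda_ == b.lambda_
        pd.testing.assert_frame_equal(a.cv_rmse_path, b.cv_rmse_path)


class TestCrossValidate:
    def test_exact_linear_outcome(self):
        df, preds = _xy_table(n=100, noise=0.0, seed=14)
        cv = cross_validate("ols", df, "y", preds, seed=0)
        assert cv.r_squared > 0.999
        assert cv.rmse < 1e-8

    def test_pure_noise_outcome(self, rng):
        df = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("abcd"))
        df["y"] = rng.normal(size=500)
        cv = cross_validate("ols", df, "y", list("abcd"), seed=0)
        assert cv.r_squared < 0.05

    def test_determinism_under_seed(self):
        df, preds = _xy_table(n=80, noise=1.0, seed=15)
        a = cross_validate("ols", df, "y", preds, seed=5)
        b = cross_validate("ols", df, "y", preds, seed=5)
        assert a.fold_rmse == b.fold_rmse and a.r_squared == b.r_squared

    def test_rmse_at_least_mae(self):
        df, preds = _xy_table(n=80, noise=1.0, seed=16)
        cv = cross_validate("ols", df, "y", preds, seed=2)
        assert cv.rmse >= cv.mae >= 0

    def test_fixed_lambda_lasso_spec(self):
        df, preds = _xy_table(n=80, noise=0.5, seed=17)
        cv = cross_validate(("lasso", 0.05), df, "y", preds, seed=2)
        assert np.isfinite(cv.rmse)

    def test_too_few_rows_rejected(self):
        df, preds = _xy_table(n=15, noise=0.5, seed=18)
        with pytest.raises(InvalidParameterError):
            cross_validate("ols", df, "y", preds, folds=10)


class TestPower:
    def test_required_sample_size_for_medium_effect(self):
        spec = PowerSpec(effect_size_f2=0.15, n_predictors=12, alpha=0.05,
                         target_power=0.80)
        assert power_regression(spec, "a_priori") == 127

    def test_post_hoc_monotone_in_n(self):
        powers = [
            regression_power(n, 12, 0.15, 0.05) for n in range(20, 200, 10)
        ]
        assert np.all(np.diff(powers) > 0)

    def test_huge_effect_minimum_design(self):
        spec = PowerSpec(effect_size_f2=1e6, n_predictors=5, alpha=0.05,
                         target_power=0.80)
        assert power_regression(spec, "a_priori") == 7  # p + 2

    def test_null_effect_rejected(self):
        with pytest.raises(InvalidParameterError):
            PowerSpec(effect_size_f2=0.0, n_predictors=12)

    def test_power_near_alpha_for_tiny_effect(self):
        assert regression_power(100, 5, 1e-9, 0.05) == pytest.approx(0.05, abs=1e-4)
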