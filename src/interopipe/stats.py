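"""Statistical stage: Spearman matrices, standardization, OLS with classical
inference, cross-validated LASSO, prediction metrics and regression power.

Conventions
-----------
* All regressions run on standardized data (mean 0, sd 1 with the n-1
  denominator, outcome included), so OLS coefficients and LASSO
  coefficients are standardized betas on a common scale.
* The LASSO objective follows the coordinate-descent convention
  ``(1/(2n))·||y - Xb||² + lambda·||b||₁``, so the smallest penalty that
  zeroes every coefficient is ``lambda_max = max_j |<x_j, y>| / n``.
* The penalty is tuned by minimising mean out-of-fold RMSE over a
  descending geometric grid; folds are reproducible from the seed.
* Cross-validated R² is the mean over folds of the squared Pearson
  correlation between out-of-fold predictions and observations; RMSE and
  MAE are pooled over all out-of-fold predictions.  R² and RMSE/MAE can
  therefore rank two models differently.
* Power for the omnibus F-test of a fixed-effects multiple regression uses
  the noncentral F distribution with noncentrality ``f² · N``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold

from .exceptions import (
    AliasingError,
    InvalidParameterError,
    UndefinedStatisticError,
)

__all__ = [
    "CorrelationMatrix",
    "RegressionResult",
    "LassoResult",
    "CVMetrics",
    "PowerSpec",
    "spearman_matrix",
    "standardize",
    "fit_ols",
    "lambda_max",
    "default_lambda_grid",
    "fit_lasso_cv",
    "cross_validate",
    "power_regression",
]


@dataclass
class CorrelationMatrix:
    rho: pd.DataFrame
    pvalues: pd.DataFrame
    n: pd.DataFrame


@dataclass
class RegressionResult:
    """OLS estimates with classical (homoskedastic) inference."""

    params: pd.Series  # includes 'Intercept'
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    rsquared: float
    fvalue: float
    df_num: int
    df_den: int
    f_pvalue: float
    nobs: int


@dataclass
class LassoResult:
    lambda_: float
    coefficients: pd.Series
    nonzero: int
    lambda_grid: np.ndarray
    cv_rmse_path: pd.DataFrame  # rows: lambda grid; columns: fold RMSE
    seed: int


@dataclass
class CVMetrics:
    r_squared: float
    rmse: float
    mae: float
    fold_r_squared: list = field(default_factory=list)
    fold_rmse: list = field(default_factory=list)
    fold_mae: list = field(default_factory=list)
    folds: int = 10
    repeats: int = 1
    seed: int = 0


@dataclass
class PowerSpec:
    effect_size_f2: float
    n_predictors: int
    alpha: float = 0.05
    target_power: float = None
    sample_size: int = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise InvalidParameterError("alpha must lie in (0, 1)")
        if self.effect_size_f2 <= 0:
            raise InvalidParameterError("effect size f² must be positive")
        if self.n_predictors < 1:
            raise InvalidParameterError("need at least one predictor")


def spearman_matrix(table: pd.DataFrame, variables=None) -> CorrelationMatrix:
    """Pairwise Spearman correlations with pairwise deletion.

    p-values use the t approximation with n-2 df (scipy).  Cells involving
    a constant variable are NaN.
    """
    if variables is None:
        variables = list(table.columns)
    k = len(variables)
    rho = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    nmat = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            pair = table[[variables[i], variables[j]]].dropna()
            n = len(pair)
            nmat[i, j] = nmat[j, i] = n
            if i == j:
                rho[i, i] = 1.0 if pair.iloc[:, 0].nunique() > 1 else np.nan
                pval[i, i] = 0.0
                continue
            if n < 3:
                continue
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if x.nunique() < 2 or y.nunique() < 2:
                continue  # undefined for constant variables
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r, p = sps.spearmanr(x, y)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    idx = pd.Index(variables)
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        pvalues=pd.DataFrame(pval, index=idx, columns=idx),
        n=pd.DataFrame(nmat, index=idx, columns=idx),
    )


def standardize(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Scale columns to mean 0, sd 1 (n-1 denominator).

    The means and sds are stored in ``df.attrs['standardize_params']`` for
    inverse mapping.  Raises on zero-variance or missing cells.
    """
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    if table[columns].isna().any().any():
        raise InvalidParameterError("standardize requires complete cases")
    out = table.copy()
    params = {}
    for c in columns:
        mu = float(table[c].mean())
        sd = float(table[c].std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise UndefinedStatisticError(f"column {c!r} has zero variance")
        out[c] = (table[c] - mu) / sd
        params[c] = (mu, sd)
    out.attrs["standardize_params"] = params
    return out


def _design(table, outcome, predictors, covariates):
    cols = list(predictors) + list(covariates)
    X = table[cols].to_numpy(dtype=float)
    y = table[outcome].to_numpy(dtype=float)
    return X, y, cols


def fit_ols(table, outcome, predictors, covariates=()) -> RegressionResult:
    """Multiple linear regression with classical se/t/p and the omnibus F.

    Solved by least squares on the intercept-augmented design; on a
    standardized table the coefficients are standardized betas.
    """
    X, y, cols = _design(table, outcome, predictors, covariates)
    n, p = X.shape
    if n <= p + 1:
        raise InvalidParameterError("need more rows than predictors + 1")

    Xd = np.hstack([np.ones((n, 1)), X])
    rank = np.linalg.matrix_rank(Xd)
    if rank < p + 1:
        # name the offending columns: those perfectly explained by the others
        bad = []
        for j, name in enumerate(cols):
            others = np.hstack([np.ones((n, 1)), np.delete(X, j, axis=1)])
            coef, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
            resid = X[:, j] - others @ coef
            ss = np.sum((X[:, j] - X[:, j].mean()) ** 2)
            if ss == 0 or np.sum(resid**2) / ss < 1e-10:
                bad.append(name)
        raise AliasingError(f"design is rank deficient; aliased columns: {bad}", bad)

    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    df_den = n - p - 1
    sigma2 = float(resid @ resid) / df_den
    cov = sigma2 * np.linalg.inv(Xd.T @ Xd)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2.0 * sps.t.sf(np.abs(tvals), df_den)

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedStatisticError("outcome has zero variance")
    r2 = 1.0 - float(resid @ resid) / ss_tot
    if r2 >= 1.0:
        fval, f_p = np.inf, 0.0
    else:
        fval = (r2 / p) / ((1.0 - r2) / df_den)
        f_p = float(sps.f.sf(fval, p, df_den))

    names = ["Intercept"] + cols
    return RegressionResult(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        tvalues=pd.Series(tvals, index=names),
        pvalues=pd.Series(pvals, index=names),
        rsquared=r2,
        fvalue=float(fval),
        df_num=p,
        df_den=df_den,
        f_pvalue=f_p,
        nobs=n,
    )


def lambda_max(table, outcome, predictors, covariates=()) -> float:
    """Smallest penalty at which every LASSO coefficient is zero."""
    X, y, _ = _design(table, outcome, predictors, covariates)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return float(np.max(np.abs(Xc.T @ yc)) / len(y))


def default_lambda_grid(lmax: float, n_points: int = 100, ratio: float = 1e-3):
    """Descending geometric grid from lambda_max down to ratio·lambda_max."""
    return np.geomspace(lmax, lmax * ratio, n_points)


def _fit_lasso(X, y, lam):
    model = Lasso(alpha=lam, fit_intercept=True, tol=1e-7, max_iter=100000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model


def _path_predict(Xtr, ytr, Xte, grid):
    """Out-of-sample predictions at every grid penalty via one warm-started path."""
    mu_x = Xtr.mean(axis=0)
    mu_y = ytr.mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, coefs, _ = lasso_path(
            Xtr - mu_x, ytr - mu_y, alphas=grid, tol=1e-7, max_iter=100000
        )
    return (Xte - mu_x) @ coefs + mu_y  # (n_te, n_grid)


def fit_lasso_cv(
    table,
    outcome,
    predictors,
    covariates=(),
    lambda_grid=None,
    folds: int = 10,
    seed: int = 0,
) -> LassoResult:
    """L1-penalized least squares with the penalty tuned by k-fold CV.

    The grid defaults to 100 geometric points from lambda_max down by three
    decades; a user grid not covering lambda_max is extended with a warning.
    The penalty minimising mean out-of-fold RMSE is selected and the final
    coefficients are refit on the full data at that penalty.
    """
    X, y, cols = _design(table, outcome, predictors, covariates)
    n = len(y)
    if folds < 2:
        raise InvalidParameterError("folds must be >= 2")
    if n < folds:
        raise InvalidParameterError(f"n = {n} smaller than {folds} folds")

    lmax = lambda_max(table, outcome, predictors, covariates)
    if lambda_grid is None:
        grid = default_lambda_grid(lmax)
    else:
        grid = np.asarray(lambda_grid, dtype=float)
        if np.any(grid <= 0) or np.any(np.diff(grid) >= 0):
            raise InvalidParameterError("lambda grid must be positive, descending")
        if grid[0] < lmax:
            warnings.warn(
                "lambda grid does not reach lambda_max; extending upward",
                stacklevel=2,
            )
            grid = np.concatenate([[lmax], grid])

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_rmse = np.empty((len(grid), folds))
    for f, (tr, te) in enumerate(kf.split(X)):
        preds = _path_predict(X[tr], y[tr], X[te], grid)
        fold_rmse[:, f] = np.sqrt(np.mean((y[te][:, None] - preds) ** 2, axis=0))

    mean_rmse = fold_rmse.mean(axis=1)
    best = int(np.argmin(mean_rmse))
    lam = float(grid[best])
    final = _fit_lasso(X, y, lam)
    coefs = pd.Series(final.coef_, index=cols)
    path = pd.DataFrame(
        fold_rmse, index=pd.Index(grid, name="lambda"),
        columns=[f"fold_{i}" for i in range(folds)],
    )
    return LassoResult(
        lambda_=lam,
        coefficients=coefs,
        nonzero=int(np.sum(np.abs(final.coef_) > 1e-12)),
        lambda_grid=grid,
        cv_rmse_path=path,
        seed=seed,
    )


def cross_validate(
    model_spec,
    table,
    outcome,
    predictors,
    covariates=(),
    folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
) -> CVMetrics:
    """Out-of-fold prediction metrics for an OLS or LASSO specification.

    ``model_spec`` is ``'ols'``, ``'lasso'`` (penalty tuned on each training
    split by an inner CV over the default grid), or ``('lasso', lam)`` for a
    fixed penalty.  R² is the mean over folds of the squared correlation
    between predictions and observations; RMSE and MAE pool all out-of-fold
    residuals.  ``repeats`` > 1 averages over repeated fold splits.
    """
    X, y, _ = _design(table, outcome, predictors, covariates)
    n = len(y)
    if n < 2 * folds:
        raise InvalidParameterError(
            f"{folds}-fold CV needs at least {2 * folds} rows (test folds of >= 2)"
        )

    fold_r2, fold_rmse, fold_mae = [], [], []
    all_resid = []
    for rep in range(repeats):
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        for tr, te in kf.split(X):
            pred = _fit_predict(model_spec, X[tr], y[tr], X[te], folds, seed)
            resid = y[te] - pred
            all_resid.append(resid)
            fold_rmse.append(float(np.sqrt(np.mean(resid**2))))
            fold_mae.append(float(np.mean(np.abs(resid))))
            if np.std(pred) > 0 and np.std(y[te]) > 0:
                fold_r2.append(float(np.corrcoef(pred, y[te])[0, 1] ** 2))
            else:
                fold_r2.append(0.0)
    pooled = np.concatenate(all_resid)
    return CVMetrics(
        r_squared=float(np.mean(fold_r2)),
        rmse=float(np.sqrt(np.mean(pooled**2))),
        mae=float(np.mean(np.abs(pooled))),
        fold_r_squared=fold_r2,
        fold_rmse=fold_rmse,
        fold_mae=fold_mae,
        folds=folds,
        repeats=repeats,
        seed=seed,
    )


def _fit_predict(model_spec, Xtr, ytr, Xte, folds, seed):
    if model_spec == "ols":
        Xd = np.hstack([np.ones((len(ytr), 1)), Xtr])
        beta, *_ = np.linalg.lstsq(Xd, ytr, rcond=None)
        return np.hstack([np.ones((len(Xte), 1)), Xte]) @ beta
    if model_spec == "lasso":
        # tune the penalty on the training split only
        Xc = Xtr - Xtr.mean(axis=0)
        yc = ytr - ytr.mean()
        lmax = float(np.max(np.abs(Xc.T @ yc)) / len(ytr))
        grid = default_lambda_grid(max(lmax, 1e-12))
        inner = KFold(n_splits=min(folds, len(ytr)), shuffle=True, random_state=seed)
        rmse = np.zeros(len(grid))
        for tr, te in inner.split(Xtr):
            preds = _path_predict(Xtr[tr], ytr[tr], Xtr[te], grid)
            rmse += np.sqrt(np.mean((ytr[te][:, None] - preds) ** 2, axis=0))
        lam = float(grid[int(np.argmin(rmse))])
        return _fit_lasso(Xtr, ytr, lam).predict(Xte)
    if isinstance(model_spec, tuple) and model_spec[0] == "lasso":
        return _fit_lasso(Xtr, ytr, float(model_spec[1])).predict(Xte)
    raise InvalidParameterError(f"unknown model spec {model_spec!r}")


def regression_power(n: int, n_predictors: int, f2: float, alpha: float) -> float:
    """Power of the omnibus F-test at sample size n (noncentrality f²·n)."""
    df_den = n - n_predictors - 1
    if df_den < 1:
        return 0.0
    crit = sps.f.isf(alpha, n_predictors, df_den)
    return float(sps.ncf.sf(crit, n_predictors, df_den, f2 * n))


def power_regression(spec: PowerSpec, mode: str = "a_priori"):
    """A-priori sample size or post-hoc power for the omnibus F-test.

    ``a_priori`` returns the smallest N (starting from the minimum estimable
    design N = p + 2) whose power reaches ``spec.target_power``; ``post_hoc``
    returns the power at ``spec.sample_size``.
    """
    p = spec.n_predictors
    if mode == "post_hoc":
        if spec.sample_size is None:
            raise InvalidParameterError("post_hoc mode requires sample_size")
        return regression_power(spec.sample_size, p, spec.effect_size_f2, spec.alpha)
    if mode == "a_priori":
        target = spec.target_power
        if target is None or not 0 < target < 1:
            raise InvalidParameterError("a_priori mode requires target_power in (0,1)")
        n = p + 2
        while regression_power(n, p, spec.effect_size_f2, spec.alpha) < target:
            n += 1
            if n > 10_000_000:
                raise InvalidParameterError("target power unattainable at this f²")
        return n
    raise InvalidParameterError(f"unknown mode {mode!r}")
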