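"""Model/results interface for the eating-behavior regression comparison.

:class:`InteroceptionModel` is constructed from a per-participant feature
table and an outcome; :meth:`InteroceptionModel.fit` runs the full
comparison — standardized OLS with classical inference, cross-validated
LASSO, and out-of-fold prediction metrics for both on shared folds — and
returns an :class:`InteroceptionResults` whose ``summary()`` prints the
familiar side-by-side coefficient table (beta, SE, t, p, LASSO beta).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import stats as ip_stats
from .exceptions import InvalidParameterError
from .scoring import COVARIATE, OUTCOMES, PREDICTORS, assemble_feature_table


class InteroceptionModel:
    """OLS vs cross-validated LASSO on a standardized feature table.

    Parameters
    ----------
    data : DataFrame
        One row per participant.  Rows with missing cells in the used
        columns are removed (listwise deletion) on construction.
    outcome : str
        Outcome column, e.g. ``'debq_emotional'``.
    predictors, covariates : sequences of str
        Default to the retained 12-predictor set plus the sex covariate.
    """

    def __init__(self, data: pd.DataFrame, outcome: str, predictors=None, covariates=None):
        self.outcome = outcome
        self.predictors = list(predictors) if predictors is not None else list(PREDICTORS)
        self.covariates = list(covariates) if covariates is not None else [COVARIATE]
        used = self.predictors + self.covariates + [outcome]
        missing = [c for c in used if c not in data.columns]
        if missing:
            raise InvalidParameterError(f"data lacks columns {missing}")
        complete = assemble_feature_table(data, required_columns=used)
        # outcome standardized along with predictors: coefficients are
        # standardized betas on a common scale for OLS and LASSO
        self.data = ip_stats.standardize(complete[used], columns=used)
        self.nobs = len(self.data)

    @classmethod
    def from_dataframe(cls, data, outcome, **kwargs):
        return cls(data, outcome, **kwargs)

    def fit(self, folds: int = 10, repeats: int = 1, seed: int = 0, lambda_grid=None):
        ols = ip_stats.fit_ols(self.data, self.outcome, self.predictors, self.covariates)
        lasso = ip_stats.fit_lasso_cv(
            self.data,
            self.outcome,
            self.predictors,
            self.covariates,
            lambda_grid=lambda_grid,
            folds=folds,
            seed=seed,
        )
        cv_ols = ip_stats.cross_validate(
            "ols", self.data, self.outcome, self.predictors, self.covariates,
            folds=folds, repeats=repeats, seed=seed,
        )
        cv_lasso = ip_stats.cross_validate(
            "lasso", self.data, self.outcome, self.predictors, self.covariates,
            folds=folds, repeats=repeats, seed=seed,
        )
        return InteroceptionResults(
            model=self, ols=ols, lasso=lasso, cv_ols=cv_ols, cv_lasso=cv_lasso
        )


@dataclass
class InteroceptionResults:
    model: InteroceptionModel
    ols: ip_stats.RegressionResult
    lasso: ip_stats.LassoResult
    cv_ols: ip_stats.CVMetrics
    cv_lasso: ip_stats.CVMetrics

    def coefficient_table(self) -> pd.DataFrame:
        """Predictors sorted by |LASSO beta|, OLS inference alongside."""
        names = self.model.predictors + self.model.covariates
        df = pd.DataFrame(
            {
                "beta": self.ols.params[names],
                "std_error": self.ols.bse[names],
                "t_value": self.ols.tvalues[names],
                "p_value": self.ols.pvalues[names],
                "lasso_beta": self.lasso.coefficients[names],
            }
        )
        return df.reindex(df["lasso_beta"].abs().sort_values(ascending=False).index)

    def cv_comparison(self) -> pd.DataFrame:
        rows = {}
        for name, cv in (("ols", self.cv_ols), ("lasso", self.cv_lasso)):
            rows[name] = {"r_squared": cv.r_squared, "rmse": cv.rmse, "mae": cv.mae}
        return pd.DataFrame(rows).T

    @property
    def lasso_outperforms(self) -> bool:
        """True when the LASSO beats OLS on out-of-fold RMSE."""
        return self.cv_lasso.rmse < self.cv_ols.rmse

    def summary(self) -> str:
        o = self.ols
        lines = [
            f"Outcome: {self.model.outcome}   n = {o.nobs}",
            f"OLS: R² = {o.rsquared:.3f}, F({o.df_num}, {o.df_den}) = "
            f"{o.fvalue:.2f}, p = {o.f_pvalue:.3f}",
            f"LASSO: lambda = {self.lasso.lambda_:.4g}, "
            f"{self.lasso.nonzero}/{len(self.model.predictors) + len(self.model.covariates)}"
            " nonzero coefficients",
            "",
            self.coefficient_table().round(4).to_string(),
            "",
            "Cross-validated prediction (shared folds):",
            self.cv_comparison().round(4).to_string(),
        ]
        return "\n".join(lines)

    def plot_cv_path(self, ax=None):
        """Mean out-of-fold RMSE against the penalty grid (log axis)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        path = self.lasso.cv_rmse_path
        mean = path.mean(axis=1)
        sd = path.std(axis=1)
        ax.plot(path.index, mean, color="C0", label="mean CV RMSE")
        ax.fill_between(path.index, mean - sd, mean + sd, alpha=0.2, color="C0")
        ax.axvline(self.lasso.lambda_, ls="--", color="C1", label="selected lambda")
        ax.set_xscale("log")
        ax.set_xlabel("lambda")
        ax.set_ylabel("out-of-fold RMSE")
        ax.legend()
        return ax


def fit_all_outcomes(data, folds=10, repeats=1, seed=0, predictors=None, covariates=None):
    """Fit the comparison for every DEBQ outcome; returns dict of results."""
    return {
        outcome: InteroceptionModel(
            data, outcome, predictors=predictors, covariates=covariates
        ).fit(folds=folds, repeats=repeats, seed=seed)
        for outcome in OUTCOMES
    }
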