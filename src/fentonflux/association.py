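"""Association of Fenton flux with reprogrammed-metabolism enrichment.

Per cancer type, the predicted Fenton-reaction flux is regressed on the RM
enrichment scores with an L1 penalty (variable selection); the penalty is
chosen by seeded K-fold cross-validation with the one-standard-error rule.
Across types the fits are condensed into a contribution summary: for each
RM, the mean positive coefficient over the types where it was selected (the
contribution score) and the fraction of types selecting it (the rate of
contribution).  A small no-intercept OLS handles the metastasis-rate model
(metastasis ~ sialic acid synthesis + degradation-gene expression).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LinearRegression, lasso_path
from sklearn.model_selection import KFold

__all__ = [
    "LassoFit",
    "ContributionSummary",
    "lasso_fit",
    "contribution_summary",
    "r_squared",
    "metastasis_regression",
    "pearson",
]


@dataclass
class LassoFit:
    coefficients: pd.Series  # per RM
    intercept: float
    lambda_chosen: float
    r2: float
    n: int
    p: int
    standardized: bool = True
    feature_mean: pd.Series | None = None
    feature_sd: pd.Series | None = None

    @property
    def selected(self) -> list[str]:
        return list(self.coefficients.index[self.coefficients != 0.0])

    def predict(self, es: pd.DataFrame) -> pd.Series:
        """Predict the response for an RM-by-sample score matrix."""
        X = es.loc[self.coefficients.index].T.astype(float)
        if self.standardized:
            X = (X - self.feature_mean) / self.feature_sd
        return X @ self.coefficients + self.intercept


@dataclass
class ContributionSummary:
    scores: pd.Series  # mean positive coefficient over selecting types
    rates: pd.Series  # fraction of types with a positive coefficient
    n_types: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "averaged_contribution_score": self.scores,
                "rate_of_contribution": self.rates,
            }
        )


def _one_se_alpha(
    X: np.ndarray,
    y: np.ndarray,
    alphas: np.ndarray,
    cv_folds: int,
    seed: int,
) -> float:
    """Largest alpha whose mean CV error is within 1 SE of the minimum."""
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    errors = np.empty((cv_folds, len(alphas)))
    for f, (tr, te) in enumerate(kf.split(X)):
        x_mean = X[tr].mean(axis=0)
        y_mean = y[tr].mean()
        _, coefs, _ = lasso_path(X[tr] - x_mean, y[tr] - y_mean, alphas=alphas)
        pred = (X[te] - x_mean) @ coefs + y_mean
        errors[f] = ((y[te][:, None] - pred) ** 2).mean(axis=0)
    mean_err = errors.mean(axis=0)
    se = errors.std(axis=0, ddof=1) / np.sqrt(cv_folds)
    best = int(np.argmin(mean_err))
    threshold = mean_err[best] + se[best]
    ok = np.flatnonzero(mean_err <= threshold)
    # alphas are descending; the smallest index is the sparsest admissible fit
    return float(alphas[ok.min()])


def lasso_fit(
    fenton: pd.Series,
    es: pd.DataFrame,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
    lam: float | None = None,
) -> LassoFit:
    """L1-penalised regression of the Fenton flux on RM enrichment scores.

    ``es`` is RM x sample; predictors are z-scored per RM by default.  The
    penalty is chosen by ``cv_folds``-fold CV with the 1-SE rule on an
    automatic geometric grid unless ``lam`` pins it directly (``lam=0``
    falls back to ordinary least squares).  Fold assignment is seeded, so
    the fit is deterministic given (data, seed).
    """
    y = fenton.to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError("constant response: degenerate fit")
    n = len(y)
    if not n >= cv_folds >= 2 and lam is None:
        raise ValueError("need n >= cv_folds >= 2")
    Xdf = es.T.astype(float)  # sample x RM
    mean = Xdf.mean()
    sd = Xdf.std(ddof=0).replace(0.0, 1.0)
    if standardize:
        Xdf = (Xdf - mean) / sd
    X = Xdf.to_numpy()

    if lam is None:
        if lambda_grid is None:
            alpha_max = np.abs(X.T @ (y - y.mean())).max() / n
            lambda_grid = alpha_max * np.logspace(0, -4, 100)
        lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
        lam = _one_se_alpha(X, y, lambda_grid, cv_folds, seed)

    if lam == 0:
        ols = LinearRegression().fit(X, y)
        coef, intercept = ols.coef_, float(ols.intercept_)
    else:
        model = Lasso(alpha=lam, max_iter=50_000)
        model.fit(X, y)
        coef, intercept = model.coef_, float(model.intercept_)
    pred = X @ coef + intercept
    sse = float(((y - pred) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    return LassoFit(
        coefficients=pd.Series(coef, index=es.index),
        intercept=intercept,
        lambda_chosen=float(lam),
        r2=1.0 - sse / sst,
        n=n,
        p=es.shape[0],
        standardized=standardize,
        feature_mean=mean,
        feature_sd=sd,
    )


def contribution_summary(
    fits: dict[str, LassoFit] | list[LassoFit],
    min_rate: float = 0.4,
    positive_only: bool = True,
) -> ContributionSummary:
    """Cross-cancer-type condensation of per-type lasso fits.

    rate = (#types with a positive coefficient) / (#types); score = mean of
    those positive coefficients.  Output keeps RMs with rate >= ``min_rate``.
    With ``positive_only=False`` any nonzero coefficient counts as selected
    and the score averages signed coefficients.
    """
    if not fits:
        raise ValueError("need at least one fit")
    fit_list = list(fits.values()) if isinstance(fits, dict) else list(fits)
    coef = pd.DataFrame({i: f.coefficients for i, f in enumerate(fit_list)})
    n_types = coef.shape[1]
    selected = coef > 0 if positive_only else coef != 0
    rates = selected.sum(axis=1) / n_types
    scores = coef.where(selected).mean(axis=1)
    keep = rates >= min_rate
    return ContributionSummary(
        scores=scores[keep].sort_values(ascending=False),
        rates=rates[keep].reindex(scores[keep].sort_values(ascending=False).index),
        n_types=n_types,
    )


def r_squared(fit: LassoFit, fenton: pd.Series, es: pd.DataFrame) -> float:
    """1 - SSE/SST of the fit on the provided data."""
    y = fenton.to_numpy(dtype=float)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("zero variance in the response")
    pred = fit.predict(es).to_numpy()
    sse = float(((y - pred) ** 2).sum())
    return 1.0 - sse / sst


def metastasis_regression(
    rates: pd.Series,
    sialic_synthesis: pd.Series,
    degradation_expr: pd.Series,
) -> tuple[pd.Series, pd.Series]:
    """No-intercept OLS: metastasis ~ b_synth * synthesis + b_degr * NEU1.

    Returns (coefficients, two-sided t-test P values), both indexed by term.
    Collinear predictors trigger a warning and a pseudo-inverse solution.
    """
    if len(rates) < 3:
        raise ValueError("need at least 3 cancer types")
    X = np.column_stack(
        [sialic_synthesis.to_numpy(dtype=float), degradation_expr.to_numpy(dtype=float)]
    )
    y = rates.to_numpy(dtype=float)
    names = ["sialic_synthesis", "degradation_expr"]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("collinear predictors; using pseudo-inverse", stacklevel=2)
        beta = np.linalg.pinv(X) @ y
        pvals = np.full(X.shape[1], np.nan)
        return pd.Series(beta, index=names), pd.Series(pvals, index=names)
    import statsmodels.api as sm

    res = sm.OLS(y, X).fit()
    return (
        pd.Series(res.params, index=names),
        pd.Series(res.pvalues, index=names),
    )


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided t-distribution P value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
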