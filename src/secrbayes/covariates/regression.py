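"""Negative-binomial regression and AIC multimodel inference.

The response is the per-pixel posterior-mean abundance — a non-integer
count surrogate — so the NB2 likelihood is evaluated through its
gamma-function continuous extension (which is what the underlying
maximum-likelihood code does anyway). AIC counts the overdispersion
parameter theta as a model parameter.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
import statsmodels.api as sm

from ..errors import ConsistencyError, DomainError

__all__ = [
    "NBFit",
    "fit_negbin",
    "akaike_weights",
    "rank_from_aic",
    "model_selection",
    "ModelRankTable",
    "gof_chi2",
    "collinearity",
]


@dataclass(frozen=True)
class NBFit:
    """A fitted NB2 log-link regression."""

    coef: np.ndarray  # intercept first
    se: np.ndarray
    pvalues: np.ndarray
    theta: float  # overdispersion: var = mu + mu^2 / theta
    theta_se: float
    loglik: float
    k: int  # parameters incl. intercept, slopes and theta
    n: int
    residual_deviance: float
    df_deviance: int  # n - (k - 1): theta not counted, matching glm-style df

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k


def _nb2_deviance(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    term2 = (y + theta) * np.log((y + theta) / (mu + theta))
    return float(2.0 * (term1 - term2).sum())


def fit_negbin(y, X, maxiter: int = 500) -> NBFit:
    """Maximum-likelihood NB2 regression with estimated theta.

    ``X`` must contain an intercept column and be full rank.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if (y < 0).any():
        raise DomainError("response must be nonnegative")
    if X.ndim != 2 or np.linalg.matrix_rank(X) < X.shape[1]:
        raise ConsistencyError("design matrix must be 2-D and full rank")
    import warnings

    model = sm.NegativeBinomial(y, X, loglike_method="nb2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=0, maxiter=maxiter)
        if not res.mle_retvals.get("converged", False):
            res = model.fit(disp=0, maxiter=maxiter, method="nm", start_params=res.params)
        if not res.mle_retvals.get("converged", False):
            res = model.fit(disp=0, maxiter=maxiter * 4, method="bfgs", start_params=res.params)
    if not res.mle_retvals.get("converged", False):
        raise ConsistencyError(
            f"NB regression failed to converge: {res.mle_retvals}"
        )
    alpha = float(res.params[-1])
    alpha = max(alpha, 1e-12)
    theta = 1.0 / alpha
    alpha_se = float(res.bse[-1])
    theta_se = alpha_se / alpha**2  # delta method for theta = 1/alpha
    k_beta = X.shape[1]
    mu = np.exp(X @ res.params[:-1])
    return NBFit(
        coef=np.asarray(res.params[:-1], dtype=float),
        se=np.asarray(res.bse[:-1], dtype=float),
        pvalues=np.asarray(res.pvalues[:-1], dtype=float),
        theta=theta,
        theta_se=theta_se,
        loglik=float(res.llf),
        k=k_beta + 1,
        n=len(y),
        residual_deviance=_nb2_deviance(y, mu, theta),
        df_deviance=len(y) - k_beta,
    )


def poisson_loglik(y, X) -> float:
    """Continuous-extension Poisson log-likelihood at the Poisson MLE.

    Companion for checking the NB -> Poisson nesting as theta grows.
    """
    y = np.asarray(y, dtype=float)
    res = sm.GLM(y, np.asarray(X, dtype=float), family=sm.families.Poisson()).fit()
    mu = res.fittedvalues
    return float((y * np.log(mu) - mu - gammaln(y + 1.0)).sum())


def akaike_weights(aic_values) -> np.ndarray:
    """w_m = exp(-delta_m / 2) normalized over the model set."""
    aic = np.asarray(aic_values, dtype=float)
    if aic.size == 0 or not np.isfinite(aic).all():
        raise DomainError("AIC values must be a nonempty finite set")
    delta = aic - aic.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass(frozen=True)
class ModelRankTable:
    """AIC ranking with Akaike weights and covariate importance."""

    table: pd.DataFrame  # model, K, aic, delta_aic, weight, cum_weight
    importance: Mapping[str, float]  # per-covariate summed weight
    fits: Mapping[str, NBFit] = field(default_factory=dict)

    def top_models(self, max_delta: float = 2.0) -> pd.DataFrame:
        return self.table[self.table["delta_aic"] <= max_delta]


def rank_from_aic(
    model_covariates: Mapping[str, Sequence[str]],
    aic_values: Mapping[str, float],
    k_values: Mapping[str, int] | None = None,
) -> ModelRankTable:
    """Build the rank table from externally supplied AICs.

    Used both by model_selection() and for re-ranking published AIC sets.
    """
    names = list(model_covariates)
    aics = np.array([aic_values[m] for m in names], dtype=float)
    w = akaike_weights(aics)
    order = np.argsort(aics, kind="stable")
    rows = []
    cum = 0.0
    for rank, i in enumerate(order, start=1):
        cum += w[i]
        rows.append(
            {
                "rank": rank,
                "model": names[i],
                "K": (k_values or {}).get(names[i], len(model_covariates[names[i]]) + 2),
                "aic": aics[i],
                "delta_aic": aics[i] - aics.min(),
                "weight": w[i],
                "cum_weight": cum,
            }
        )
    covs = sorted({c for cs in model_covariates.values() for c in cs})
    importance = {
        c: float(sum(w[i] for i, m in enumerate(names) if c in model_covariates[m]))
        for c in covs
    }
    return ModelRankTable(table=pd.DataFrame(rows), importance=importance)


def model_selection(
    y, covariate_table: pd.DataFrame, covariate_names: Sequence[str] | None = None,
    include_null: bool = False,
) -> ModelRankTable:
    """Fit every non-empty covariate subset and rank by AIC.

    Three covariates yield exactly 7 models; the intercept-only model is
    excluded by default (``include_null`` adds it). Non-convergent subsets
    are flagged and excluded from the weights.
    """
    names = list(covariate_names or covariate_table.columns)
    subsets: list[tuple[str, ...]] = []
    if include_null:
        subsets.append(())
    for r in range(1, len(names) + 1):
        subsets.extend(itertools.combinations(names, r))

    fits: dict[str, NBFit] = {}
    model_covs: dict[str, tuple[str, ...]] = {}
    failed: list[str] = []
    for covs in subsets:
        label = " + ".join(covs) if covs else "1"
        X = np.column_stack(
            [np.ones(len(covariate_table))]
            + [covariate_table[c].to_numpy(dtype=float) for c in covs]
        )
        try:
            fits[label] = fit_negbin(y, X)
            model_covs[label] = covs
        except ConsistencyError:
            failed.append(label)
    if not fits:
        raise ConsistencyError("no candidate model converged")
    ranked = rank_from_aic(
        model_covs,
        {m: f.aic for m, f in fits.items()},
        {m: f.k for m, f in fits.items()},
    )
    if failed:
        t = ranked.table.copy()
        t.attrs["failed_models"] = failed
        ranked = ModelRankTable(table=t, importance=ranked.importance, fits=fits)
    else:
        ranked = ModelRankTable(table=ranked.table, importance=ranked.importance, fits=fits)
    return ranked


def gof_chi2(residual_deviance: float, df: int) -> float:
    """Upper-tail chi-square probability of the residual deviance."""
    if df < 1:
        raise DomainError("df must be >= 1")
    if residual_deviance < 0:
        raise DomainError("deviance must be nonnegative")
    return float(stats.chi2.sf(residual_deviance, df))


def collinearity(X, threshold: float = 0.7) -> tuple[np.ndarray, list[tuple[int, int, float]]]:
    """Pairwise Pearson correlations with flags above the threshold.

    Zero-variance columns yield NaN rows/columns, flagged with r = NaN.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise DomainError("need at least two columns")
    sds = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    flags: list[tuple[int, int, float]] = []
    p = X.shape[1]
    for i in range(p):
        for j in range(i + 1, p):
            r = corr[i, j]
            if sds[i] == 0 or sds[j] == 0:
                flags.append((i, j, float("nan")))
            elif abs(r) > threshold:
                flags.append((i, j, float(r)))
    return corr, flags
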