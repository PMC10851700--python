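"""Binomial mixed models with a participant random intercept.

Two interchangeable estimation routes are exposed:

* ``method="quadrature"`` (default): maximum marginal likelihood for a
  logistic model with a Gaussian random intercept per participant, the
  integral over the intercept evaluated by Gauss--Hermite quadrature (a
  Laplace-type approximation that is exact as the node count grows).
* ``method="fixed"``: the fallback contract — per-participant fixed
  intercepts estimated by ordinary logistic ML (statsmodels GLM), useful as
  an independent check and when the variance component is degenerate.

Both return Wald tests for the fixed effects, the maximized log-likelihood
and AIC (−2·loglik + 2·k counting fixed effects plus, for the quadrature
route, one variance parameter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import log_expit


@dataclass
class MixedLogitResult:
    params: pd.Series  # fixed effects
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    random_effect_sd: float
    loglik: float
    aic: float
    n_params: int
    method: str
    converged: bool


_GH_NODES = 25


def _group_slices(groups: np.ndarray) -> list[np.ndarray]:
    uniq = pd.unique(groups)
    return [np.flatnonzero(groups == g) for g in uniq]


def _marginal_loglik(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                     slices: list[np.ndarray], nodes: np.ndarray,
                     log_wts: np.ndarray) -> float:
    beta, log_sd = theta[:-1], theta[-1]
    sd = np.exp(log_sd)
    eta0 = X @ beta
    total = 0.0
    shift = np.sqrt(2.0) * sd * nodes  # (K,)
    for idx in slices:
        # (n_i, K) log-likelihood of each trial at each node
        eta = eta0[idx][:, None] + shift[None, :]
        ll = np.where(y[idx][:, None] > 0, log_expit(eta), log_expit(-eta))
        total += np.logaddexp.reduce(log_wts + ll.sum(axis=0))
    return total


def fit_mixed_logit(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                    names: list[str] | None = None,
                    method: str = "quadrature",
                    n_nodes: int = _GH_NODES) -> MixedLogitResult:
    """Fit ``logit P(y=1) = X beta + u_group`` with ``u ~ N(0, sd^2)``.

    ``X`` must include an intercept column if one is wanted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(float)
    groups = np.asarray(groups)
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]

    if method == "fixed":
        return _fit_fixed_intercepts(X, y, groups, names)
    if method != "quadrature":
        raise ValueError(f"unknown method: {method}")

    gh_x, gh_w = np.polynomial.hermite.hermgauss(n_nodes)
    log_wts = np.log(gh_w) - 0.5 * np.log(np.pi)
    slices = _group_slices(groups)

    # start from the pooled logistic fit, moderate random-intercept SD
    pooled = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    theta0 = np.concatenate([pooled.params, [np.log(0.3)]])

    def negll(theta: np.ndarray) -> float:
        return -_marginal_loglik(theta, X, y, slices, gh_x, log_wts)

    bounds = [(None, None)] * p + [(-6.0, 3.0)]
    res = optimize.minimize(negll, theta0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-11})
    theta = res.x
    loglik = -res.fun

    # Wald SEs from the numerical Hessian of the fixed-effect block
    hess = _numeric_hessian(negll, theta)
    bse = np.full(p, np.nan)
    try:
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)[:p]
        bse = np.sqrt(np.where(diag > 0, diag, np.nan))
    except np.linalg.LinAlgError:
        try:
            cov = np.linalg.inv(hess[:p, :p])
            diag = np.diag(cov)
            bse = np.sqrt(np.where(diag > 0, diag, np.nan))
        except np.linalg.LinAlgError:
            pass
    params = pd.Series(theta[:p], index=names)
    bse = pd.Series(bse, index=names)
    z = params / bse
    pvals = pd.Series(2 * stats.norm.sf(np.abs(z)), index=names)
    k = p + 1
    return MixedLogitResult(
        params=params, bse=bse, zvalues=z, pvalues=pvals,
        random_effect_sd=float(np.exp(theta[-1])),
        loglik=float(loglik), aic=float(-2 * loglik + 2 * k),
        n_params=k, method="quadrature", converged=bool(res.success),
    )


def _numeric_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    f0 = f(x)
    steps = eps * np.maximum(1.0, np.abs(x))
    fp = np.empty(n)
    for i in range(n):
        xi = x.copy()
        xi[i] += steps[i]
        fp[i] = f(xi)
    for i in range(n):
        for j in range(i, n):
            xij = x.copy()
            xij[i] += steps[i]
            xij[j] += steps[j]
            H[i, j] = H[j, i] = (
                (f(xij) - fp[i] - fp[j] + f0) / (steps[i] * steps[j])
            )
    return H


def _fit_fixed_intercepts(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                          names: list[str]) -> MixedLogitResult:
    """Fallback: per-participant fixed intercepts, ordinary logistic ML.

    The model drops any global intercept column from ``X`` (a column of
    ones) since the participant dummies span it.
    """
    uniq = pd.unique(groups)
    dummies = np.column_stack([(groups == g).astype(float) for g in uniq])
    keep = [i for i in range(X.shape[1])
            if not np.allclose(X[:, i], X[0, i])]  # drop constant columns
    Xf = np.hstack([X[:, keep], dummies])
    model = sm.GLM(y, Xf, family=sm.families.Binomial())
    fit = model.fit(maxiter=200)
    p = len(keep)
    kept_names = [names[i] for i in keep]
    params = pd.Series(fit.params[:p], index=kept_names)
    bse = pd.Series(fit.bse[:p], index=kept_names)
    z = params / bse
    pvals = pd.Series(2 * stats.norm.sf(np.abs(z)), index=kept_names)
    intercepts = np.asarray(fit.params[p:])
    k = Xf.shape[1]
    # re-insert dropped (constant) columns as NaN so callers see all names
    for i in range(X.shape[1]):
        if i not in keep:
            params[names[i]] = np.nan
            bse[names[i]] = np.nan
            z[names[i]] = np.nan
            pvals[names[i]] = np.nan
    return MixedLogitResult(
        params=params, bse=bse, zvalues=z, pvalues=pvals,
        random_effect_sd=float(np.std(intercepts, ddof=1))
        if len(intercepts) > 1 else 0.0,
        loglik=float(fit.llf), aic=float(-2 * fit.llf + 2 * k),
        n_params=k, method="fixed", converged=bool(fit.converged),
    )


def likelihood_ratio_test(ll_full: float, ll_reduced: float,
                          df: int) -> dict:
    """Chi-square LRT of a nested pair of fits."""
    lr = max(0.0, 2.0 * (ll_full - ll_reduced))
    return {"statistic": float(lr), "df": int(df),
            "p_value": float(stats.chi2.sf(lr, df))}
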