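"""Global logistic and Poisson regression by maximum likelihood.

Both families are fitted by iteratively reweighted least squares (IRLS)
with step-halving, so the log-likelihood is non-decreasing across
iterations. A fit is declared converged when the relative change in
log-likelihood drops below 1e-8 or the score norm ||X'(y - yhat)||_inf
falls below 1e-8, within 100 iterations. Covariate selection uses
bidirectional stepwise search on Wald z-test p-values at a significance
level alpha (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .data_core import SpatialDataset

FAMILIES = ("logistic", "poisson")
#: response conventionally paired with each family
FAMILY_RESPONSE = {"logistic": "odw", "poisson": "ndw"}

_ETA_MAX = 30.0  # linear-predictor clip; exp(30) ~ 1e13, beyond any stand density


def _check_family(family: str) -> None:
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")


def inverse_link(eta: np.ndarray, family: str) -> np.ndarray:
    """Mean response from the linear predictor: expit (logistic) or exp (poisson)."""
    _check_family(family)
    eta = np.clip(eta, -_ETA_MAX, _ETA_MAX)
    if family == "logistic":
        return 1.0 / (1.0 + np.exp(-eta))
    return np.exp(eta)


def mean_derivative(eta: np.ndarray, family: str) -> np.ndarray:
    """d mu / d eta, used as the IRLS working weight (canonical links)."""
    mu = inverse_link(eta, family)
    if family == "logistic":
        return mu * (1.0 - mu)
    return mu


def log_likelihood(y: np.ndarray, mu: np.ndarray, family: str, weights: np.ndarray | None = None) -> float:
    """(Weighted) log-likelihood of the observed responses at fitted means."""
    _check_family(family)
    eps = 1e-12
    if family == "logistic":
        ll = y * np.log(mu + eps) + (1.0 - y) * np.log(1.0 - mu + eps)
    else:
        ll = y * np.log(mu + eps) - mu - gammaln(np.asarray(y) + 1.0)
    if weights is not None:
        ll = weights * ll
    return float(np.sum(ll))


@dataclass
class GlobalFit:
    """A converged (or flagged) maximum-likelihood GLM fit.

    ``beta`` holds the intercept first, then one coefficient per entry of
    ``covariate_names``. ``cov_beta`` is the inverse Fisher information,
    from which Wald standard errors are derived.
    """

    family: str
    beta: np.ndarray
    covariate_names: list[str]
    log_likelihood: float
    converged: bool
    n_iter: int
    cov_beta: np.ndarray | None = None
    message: str = ""

    @property
    def se(self) -> np.ndarray:
        if self.cov_beta is None:
            raise ValueError("covariance unavailable")
        return np.sqrt(np.diag(self.cov_beta))

    def wald_pvalues(self) -> np.ndarray:
        z = self.beta / self.se
        return 2.0 * stats.norm.sf(np.abs(z))


def _design(X: pd.DataFrame | np.ndarray, names: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = list(X.columns) if names is None else names
        missing = [c for c in names if c not in X.columns]
        if missing:
            raise ValueError(f"covariate column(s) not in X: {missing}")
        Xm = X[names].to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        names = [f"x{i}" for i in range(Xm.shape[1])] if names is None else names
    return np.column_stack([np.ones(len(Xm)), Xm]), names


def irls(
    Xd: np.ndarray,
    y: np.ndarray,
    family: str,
    obs_weights: np.ndarray | None = None,
    beta0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    ll_trace: list | None = None,
) -> tuple[np.ndarray, float, bool, int, np.ndarray]:
    """Weighted IRLS core shared by the global and geographically weighted fits.

    Returns ``(beta, loglik, converged, n_iter, cov_beta)``. ``obs_weights``
    are non-negative per-observation weights (kernel weights for local fits);
    ``beta0`` warm-starts the iteration. Step-halving guarantees the weighted
    log-likelihood never decreases between iterations.
    """
    _check_family(family)
    y = np.asarray(y, dtype=float)
    n, p = Xd.shape
    w = np.ones(n) if obs_weights is None else np.asarray(obs_weights, dtype=float)

    if np.linalg.matrix_rank(Xd * np.sqrt(w)[:, None]) < p:
        corr = np.corrcoef(Xd[:, 1:], rowvar=False) if p > 2 else None
        raise np.linalg.LinAlgError(
            "rank-deficient (weighted) design matrix; collinear or degenerate columns"
            + (f" (covariate correlations:\n{np.round(corr, 3)})" if corr is not None else "")
        )

    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    eta = Xd @ beta
    mu = inverse_link(eta, family)
    ll = log_likelihood(y, mu, family, w)
    if ll_trace is not None:
        ll_trace.append(ll)

    converged = False
    it = 0
    cov = None
    for it in range(1, max_iter + 1):
        W = w * mean_derivative(eta, family)
        W = np.maximum(W, 1e-10)
        z = eta + (y - mu) / np.maximum(mean_derivative(eta, family), 1e-10)
        WX = Xd * W[:, None]
        A = Xd.T @ WX
        b = WX.T @ z
        try:
            beta_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(A, b, rcond=None)[0]

        # step-halving: shrink toward the previous iterate until ll improves
        step = beta_new - beta
        ll_new = -np.inf
        for _ in range(30):
            cand = beta + step
            mu_c = inverse_link(Xd @ cand, family)
            ll_new = log_likelihood(y, mu_c, family, w)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        beta = beta + step
        eta = Xd @ beta
        mu = inverse_link(eta, family)

        score = Xd.T @ (w * (y - mu))
        rel = abs(ll_new - ll) / (abs(ll) + 1e-10)
        ll = ll_new
        if ll_trace is not None:
            ll_trace.append(ll)
        if rel < tol or np.max(np.abs(score)) < tol:
            converged = True
            break

    W = np.maximum(w * mean_derivative(eta, family), 1e-10)
    A = Xd.T @ (Xd * W[:, None])
    try:
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(A)
    return beta, ll, converged, it, cov


def fit_glm(
    ds: SpatialDataset,
    family: str,
    response: str | None = None,
    covariates: list[str] | None = None,
) -> GlobalFit:
    """Fit a global (spatially stationary) GLM by maximum likelihood.

    ``response`` defaults to the family's conventional pairing
    (logistic -> odw, poisson -> ndw).
    """
    _check_family(family)
    response = FAMILY_RESPONSE[family] if response is None else response
    y = ds.response(response)
    Xd, names = _design(ds.X, covariates)
    beta, ll, converged, n_iter, cov = irls(Xd, y, family)
    msg = ""
    if family == "logistic" and Xd.shape[1] > 1:
        mu = inverse_link(Xd @ beta, family)
        degenerate = (np.min(mu[y == 1], initial=1.0) > 1 - 1e-6
                      and np.max(mu[y == 0], initial=0.0) < 1e-6)
        if degenerate and np.max(np.abs(beta)) > 20:
            converged = False
            msg = "possible complete separation: fitted probabilities degenerate"
    if not converged and not msg:
        msg = "IRLS did not converge within iteration limit"
    return GlobalFit(
        family=family,
        beta=beta,
        covariate_names=names,
        log_likelihood=ll,
        converged=converged,
        n_iter=n_iter,
        cov_beta=cov,
        message=msg,
    )


def predict_glm(fit: GlobalFit, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Mean response at new covariates through the family's inverse link."""
    Xd, _ = _design(X, fit.covariate_names if isinstance(X, pd.DataFrame) else None)
    if Xd.shape[1] != len(fit.beta):
        raise ValueError(
            f"X has {Xd.shape[1] - 1} columns but fit expects {len(fit.beta) - 1}"
        )
    return inverse_link(Xd @ fit.beta, fit.family)


def stepwise_select(
    ds: SpatialDataset,
    candidates: list[str],
    family: str,
    response: str | None = None,
    alpha: float = 0.05,
    max_rounds: int = 50,
) -> list[str]:
    """Bidirectional stepwise covariate selection on Wald p-values.

    Forward step adds the candidate with the smallest p-value below
    ``alpha``; backward step drops any retained variable whose p-value has
    risen to ``alpha`` or above; the two alternate to a fixed point. Ties
    break lexicographically on column name, making the result
    deterministic.
    """
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    selected: list[str] = []
    remaining = sorted(candidates)

    def pvalue_of(cols: list[str], target: str) -> float:
        fit = fit_glm(ds, family, response, covariates=cols)
        return float(fit.wald_pvalues()[1 + cols.index(target)])

    for _ in range(max_rounds):
        changed = False
        # forward: most significant addition under alpha
        best_p, best_c = None, None
        for c in remaining:
            p = pvalue_of(sorted(selected + [c]), c)
            if p < alpha and (best_p is None or p < best_p or (p == best_p and c < best_c)):
                best_p, best_c = p, c
        if best_c is not None:
            selected = sorted(selected + [best_c])
            remaining.remove(best_c)
            changed = True
        # backward: drop anything no longer significant
        while selected:
            fit = fit_glm(ds, family, response, covariates=selected)
            pv = fit.wald_pvalues()[1:]
            worst = int(np.argmax(pv))
            if pv[worst] >= alpha:
                dropped = selected.pop(worst)
                remaining = sorted(remaining + [dropped])
                changed = True
            else:
                break
        if not changed:
            break
    return selected
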