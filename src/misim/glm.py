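"""Logistic regression by iteratively reweighted least squares.

A deliberately small fitter with glm.fit-like semantics: a hard iteration
cap, step-halving, and no remedial action on (quasi-)separation — the fit
returns whatever estimate the capped iteration reached, with a convergence
flag. Under extreme missingness the analysis pipeline *wants* those erratic
estimates: pooling them is the phenomenon under study, so the fitter must
never raise where a capped iteration can return. An optional ridge penalty
is available for users who prefer stabilised fits; it is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit


@dataclass(frozen=True)
class LogisticFit:
    coef: np.ndarray          # (p,) including intercept first
    se: np.ndarray            # (p,) from inverse observed information
    converged: bool
    n_iter: int
    loglik: float

    @property
    def flagged(self) -> bool:
        """True when the fit is suspect: iteration cap hit or runaway coefficients."""
        return (not self.converged) or bool(np.any(np.abs(self.coef) > 50)) \
            or not np.all(np.isfinite(self.se))


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(X: np.ndarray, y: np.ndarray, *, add_intercept: bool = True,
                 max_iter: int = 100, tol: float = 1e-10,
                 ridge: float = 0.0) -> LogisticFit:
    """Maximum-likelihood logistic fit of binary ``y`` on ``X``.

    Convergence is declared when the relative change in log-likelihood
    falls below ``tol``. Standard errors come from the inverse observed
    information at the final iterate. ``ridge`` adds a quadratic penalty
    ``ridge * ||beta||^2 / 2`` (intercept included) to the score and
    information; the default 0 is the plain MLE.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("y must be coded 0/1")
    if classes.size < 2:
        raise ValueError("outcome has a single class; logistic fit undefined")
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
    n, p = X.shape

    beta = np.zeros(p)
    # start the intercept at the marginal log-odds
    ybar = y.mean()
    beta[0] = np.log(ybar / (1.0 - ybar)) if add_intercept else 0.0
    eta = X @ beta
    ll = _loglik(eta, y) - 0.5 * ridge * beta @ beta
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        w = mu * (1.0 - mu)
        # Newton step on the (possibly penalised) log-likelihood
        info = X.T @ (X * w[:, None])
        if ridge:
            info = info + ridge * np.eye(p)
        score = X.T @ (y - mu)
        if ridge:
            score = score - ridge * beta
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # step-halving keeps the likelihood monotone even near separation
        new_ll = -np.inf
        for _ in range(30):
            cand = beta + step
            cand_eta = X @ cand
            new_ll = _loglik(cand_eta, y) - 0.5 * ridge * cand @ cand
            if np.isfinite(new_ll) and new_ll >= ll - 1e-12:
                break
            step = step / 2.0
        beta, eta = cand, cand_eta
        if abs(new_ll - ll) < tol * (abs(ll) + tol):
            ll = new_ll
            converged = True
            break
        ll = new_ll

    mu = expit(eta)
    w = mu * (1.0 - mu)
    info = X.T @ (X * w[:, None])
    if ridge:
        info = info + ridge * np.eye(p)
    with np.errstate(invalid="ignore"):
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
    return LogisticFit(coef=beta, se=se, converged=converged, n_iter=it, loglik=ll)


def logistic_covariance(X: np.ndarray, beta: np.ndarray, *,
                        add_intercept: bool = True, ridge: float = 0.0) -> np.ndarray:
    """Inverse observed information at ``beta`` (for posterior draws)."""
    X = np.asarray(X, dtype=float)
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
    eta = X @ beta
    mu = expit(eta)
    w = mu * (1.0 - mu)
    info = X.T @ (X * w[:, None])
    if ridge:
        info = info + ridge * np.eye(X.shape[1])
    return np.linalg.inv(info)
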