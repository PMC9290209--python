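"""Analysis-model fitting, Rubin's Rules pooling, and Barnard-Rubin intervals.

Each complete dataset is analysed with the same multivariable logistic
model (outcome on all ten covariates plus intercept). The M per-dataset
estimates are pooled with Rubin's Rules; confidence intervals use the
Barnard-Rubin small-sample degrees of freedom, never a normal
approximation. Non-converged or runaway per-dataset fits are pooled like
any other and only counted — discarding them would hide exactly the
erratic-estimate behaviour the simulation is designed to measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .glm import fit_logistic


@dataclass
class PooledFit:
    """Rubin's-Rules summary over M complete-data fits, per coefficient."""

    estimate: np.ndarray         # Q-bar, (p,)
    within: np.ndarray           # W-bar, mean squared SE
    between: np.ndarray          # B, sample variance of estimates
    total: np.ndarray            # T = W-bar + (1 + 1/M) B
    M: int
    df: np.ndarray | None = None       # Barnard-Rubin nu
    ci_lo: np.ndarray | None = None
    ci_hi: np.ndarray | None = None
    n_flagged_fits: int = 0

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(self.total)


def fit_analysis_model(X: np.ndarray, y: np.ndarray, *, ridge: float = 0.0):
    """Logistic MLE of the outcome on the 10 covariates.

    Returns ``(coef, se, converged)`` where ``converged`` is False when the
    iteration cap was hit or any coefficient ran past 50 in absolute value.
    """
    fit = fit_logistic(X, y, max_iter=100, tol=1e-10, ridge=ridge)
    return fit.coef, fit.se, not fit.flagged


def pool_rubin(estimates: np.ndarray, ses: np.ndarray) -> PooledFit:
    """Rubin's Rules: Q-bar, W-bar, B, and T = W-bar + (1 + 1/M) B."""
    estimates = np.atleast_2d(np.asarray(estimates, dtype=float))
    ses = np.atleast_2d(np.asarray(ses, dtype=float))
    if estimates.shape != ses.shape:
        raise ValueError("estimates and ses must have identical shapes")
    M = estimates.shape[0]
    if M < 2:
        raise ValueError("Rubin's Rules require M >= 2 imputed datasets")
    qbar = estimates.mean(axis=0)
    wbar = (ses ** 2).mean(axis=0)
    b = estimates.var(axis=0, ddof=1)
    total = wbar + (1.0 + 1.0 / M) * b
    return PooledFit(estimate=qbar, within=wbar, between=b, total=total, M=M)


def barnard_rubin_df(wbar: np.ndarray, between: np.ndarray, total: np.ndarray,
                     M: int, n_sample: int, n_params: int) -> np.ndarray:
    """Barnard-Rubin small-sample degrees of freedom, vectorised per term.

    With lambda = (1 + 1/M) B / T: nu_old = (M - 1) / lambda^2,
    nu_obs = ((nu_com + 1)/(nu_com + 3)) * nu_com * (1 - lambda) for
    complete-data df nu_com = n - p, and nu = (1/nu_old + 1/nu_obs)^{-1}.
    When B = 0 (lambda = 0) the classical term drops out and nu = nu_obs.
    """
    nu_com = n_sample - n_params
    if nu_com <= 0:
        raise ValueError(
            f"complete-data degrees of freedom n - p = {nu_com} must be positive")
    lam = (1.0 + 1.0 / M) * between / total
    nu_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - lam)
    with np.errstate(divide="ignore"):
        nu_old = (M - 1.0) / lam ** 2
    nu = 1.0 / (1.0 / nu_old + 1.0 / nu_obs)
    return np.where(lam == 0.0, nu_obs, nu)


def barnard_rubin_ci(pooled: PooledFit, n_sample: int, n_params: int,
                     level: float = 0.95) -> PooledFit:
    """Attach Barnard-Rubin degrees of freedom and t-based CIs to a pooled fit."""
    if np.any(pooled.total <= 0):
        raise ValueError("total variance must be positive for interval construction")
    nu = barnard_rubin_df(pooled.within, pooled.between, pooled.total,
                          pooled.M, n_sample, n_params)
    tq = stats.t.ppf(0.5 + level / 2.0, nu)
    half = tq * np.sqrt(pooled.total)
    pooled.df = nu
    pooled.ci_lo = pooled.estimate - half
    pooled.ci_hi = pooled.estimate + half
    return pooled


def pool_analysis(imputed, *, n_params: int | None = None, level: float = 0.95,
                  ridge: float = 0.0) -> PooledFit:
    """Fit the analysis model in every complete dataset and pool.

    Convenience wrapper used by the simulation engine: takes an
    :class:`~misim.impute.ImputedData`, fits the 11-term logistic model in
    each of its M datasets, pools with Rubin's Rules, and attaches
    Barnard-Rubin intervals.
    """
    estimates, ses, flags = [], [], 0
    for X, y in imputed.datasets():
        coef, se, ok = fit_analysis_model(X, y, ridge=ridge)
        estimates.append(coef)
        ses.append(se)
        flags += 0 if ok else 1
    pooled = pool_rubin(np.array(estimates), np.array(ses))
    p = n_params if n_params is not None else len(pooled.estimate)
    pooled = barnard_rubin_ci(pooled, n_sample=imputed.sample.n, n_params=p,
                              level=level)
    pooled.n_flagged_fits = flags + (1 if imputed.imputation_flagged else 0)
    return pooled
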