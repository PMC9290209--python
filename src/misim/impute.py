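"""Univariate multiple imputation of a single incomplete covariate.

Three proper-imputation methods, implemented from first principles:

``norm``
    Bayesian linear regression. Per imputed dataset the residual variance
    is drawn from its scaled inverse-chi-square posterior, the coefficients
    from a normal centred at the least-squares estimate, and each missing
    value as a predicted mean plus fresh Gaussian noise.

``pmm``
    Predictive mean matching with Type-1 matching: donors are scored with
    the posterior-mode coefficients, recipients with the drawn
    coefficients; each recipient copies the observed value of one of its
    ``donor_pool_k`` nearest donors, chosen uniformly (distance ties are
    broken uniformly at random). PMM never fabricates a value.

``logreg``
    Posterior-draw logistic regression for a binary target: coefficients
    are drawn from the asymptotic normal around the MLE, and each missing
    value from a Bernoulli at its drawn probability.

The imputation model always uses the nine complete covariates plus the
analysis outcome as predictors. Observed values are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import fit_logistic, logistic_covariance
from .population import AnalysisSample


def choose_M(p_missing: float) -> int:
    """Number of imputed datasets: the percentage of missing subjects.

    Rounds ``100 * p_missing`` half away from zero and floors the result
    at 2 (Rubin's Rules need at least two datasets).
    """
    if not 0.0 < p_missing < 1.0:
        raise ValueError(f"p_missing must lie in (0, 1), got {p_missing}")
    m = int(np.floor(100.0 * p_missing + 0.5))
    return max(m, 2)


@dataclass(frozen=True)
class ImputationSpec:
    method: str                      # "norm" | "pmm" | "logreg"
    M: int
    donor_pool_k: int = 5            # pmm only
    seed: int | np.random.SeedSequence | None = None
    ridge: float = 0.0               # optional stabilisation of logistic fits

    def __post_init__(self) -> None:
        if self.method not in ("norm", "pmm", "logreg"):
            raise ValueError(f"unknown imputation method {self.method!r}")
        if self.M < 2:
            raise ValueError("M must be at least 2")
        if self.donor_pool_k < 1:
            raise ValueError("donor_pool_k must be positive")


@dataclass
class ImputedData:
    """M completed copies of the target column over one analysis sample."""

    sample: AnalysisSample
    target_values: np.ndarray        # (M, n) completed target column
    method: str
    imputation_flagged: bool = False  # any suspect imputation-model fit

    @property
    def M(self) -> int:
        return self.target_values.shape[0]

    def dataset(self, m: int) -> tuple[np.ndarray, np.ndarray]:
        """The m-th complete dataset as ``(X, y)``."""
        X = self.sample.X.copy()
        X[:, self.sample.target_index] = self.target_values[m]
        return X, self.sample.y

    def datasets(self):
        for m in range(self.M):
            yield self.dataset(m)


def _predictor_matrix(sample: AnalysisSample) -> np.ndarray:
    """Intercept + the nine complete covariates + the analysis outcome."""
    keep = [j for j in range(sample.X.shape[1]) if j != sample.target_index]
    return np.column_stack([np.ones(sample.n), sample.X[:, keep], sample.y])


def _check_rank(R: np.ndarray) -> None:
    diag = np.abs(np.diag(R))
    bad = np.where(diag < 1e-10 * diag.max())[0]
    if bad.size:
        raise ValueError(
            f"imputation predictor matrix is rank deficient (collinear design "
            f"columns {bad.tolist()}, intercept = column 0)")


def _norm_draw(Xo: np.ndarray, to: np.ndarray, rng: np.random.Generator):
    """One posterior draw (beta_hat, beta_star, sigma_star) for the linear model."""
    n_obs, p = Xo.shape
    Q, R = np.linalg.qr(Xo)
    _check_rank(R)
    beta_hat = np.linalg.solve(R, Q.T @ to)
    resid = to - Xo @ beta_hat
    rss = float(resid @ resid)
    nu = n_obs - p
    sigma2_star = rss / rng.chisquare(nu)
    # beta* = beta_hat + sigma* R^{-1} z since (X'X)^{-1} = R^{-1} R^{-T}
    z = rng.standard_normal(p)
    beta_star = beta_hat + np.sqrt(sigma2_star) * np.linalg.solve(R, z)
    return beta_hat, beta_star, np.sqrt(sigma2_star)


def _observed_split(sample: AnalysisSample, min_obs: int):
    obs = sample.observed
    n_obs = int(obs.sum())
    if n_obs < min_obs:
        raise ValueError(
            f"only {n_obs} rows observe the target; at least {min_obs} required")
    return obs, ~obs


def impute_norm(sample: AnalysisSample, spec: ImputationSpec) -> ImputedData:
    """Bayesian linear-regression imputation of a continuous target."""
    Z = _predictor_matrix(sample)
    obs, mis = _observed_split(sample, Z.shape[1] + 1)
    rng = np.random.default_rng(spec.seed)
    t = sample.X[:, sample.target_index]
    out = np.tile(t, (spec.M, 1))
    n_mis = int(mis.sum())
    for m in range(spec.M):
        _, beta_star, sigma_star = _norm_draw(Z[obs], t[obs], rng)
        if n_mis:
            out[m, mis] = Z[mis] @ beta_star + sigma_star * rng.standard_normal(n_mis)
    return ImputedData(sample=sample, target_values=out, method="norm")


def _nearest_donors(yhat_recip: np.ndarray, yhat_donor: np.ndarray, k: int,
                    rng: np.random.Generator, chunk: int = 2000) -> np.ndarray:
    """Indices of each recipient's k nearest donors by |predicted difference|.

    Exact ties are broken uniformly at random via an infinitesimal uniform
    jitter (too small to reorder any genuinely distinct distances).
    Recipients are processed in chunks so the distance matrix never exceeds
    ``chunk * n_donors`` entries.
    """
    n_mis, n_obs = yhat_recip.size, yhat_donor.size
    scale = max(float(np.abs(yhat_donor).max(initial=0.0)),
                float(np.abs(yhat_recip).max(initial=0.0)), 1.0)
    eps = 1e-10 * scale
    out = np.empty((n_mis, k), dtype=np.intp)
    for lo in range(0, n_mis, chunk):
        hi = min(lo + chunk, n_mis)
        d = np.abs(yhat_recip[lo:hi, None] - yhat_donor[None, :])
        d += rng.random(d.shape) * eps
        out[lo:hi] = np.argpartition(d, k - 1, axis=1)[:, :k]
    return out


def impute_pmm(sample: AnalysisSample, spec: ImputationSpec) -> ImputedData:
    """Type-1 predictive mean matching with a fixed donor pool."""
    Z = _predictor_matrix(sample)
    obs, mis = _observed_split(sample, Z.shape[1] + 1)
    n_obs = int(obs.sum())
    if spec.donor_pool_k > n_obs:
        raise ValueError(
            f"donor_pool_k={spec.donor_pool_k} exceeds the {n_obs} observed rows")
    rng = np.random.default_rng(spec.seed)
    t = sample.X[:, sample.target_index]
    t_obs = t[obs]
    out = np.tile(t, (spec.M, 1))
    n_mis = int(mis.sum())
    for m in range(spec.M):
        beta_hat, beta_star, _ = _norm_draw(Z[obs], t_obs, rng)
        if not n_mis:
            continue
        yhat_donor = Z[obs] @ beta_hat        # posterior mode for donors
        yhat_recip = Z[mis] @ beta_star       # drawn coefficients for recipients
        pool = _nearest_donors(yhat_recip, yhat_donor, spec.donor_pool_k, rng)
        pick = rng.integers(spec.donor_pool_k, size=n_mis)
        out[m, mis] = t_obs[pool[np.arange(n_mis), pick]]
    return ImputedData(sample=sample, target_values=out, method="pmm")


def impute_logreg(sample: AnalysisSample, spec: ImputationSpec) -> ImputedData:
    """Posterior-draw logistic imputation of a binary target."""
    Z = _predictor_matrix(sample)
    obs, mis = _observed_split(sample, Z.shape[1] + 1)
    t = sample.X[:, sample.target_index]
    t_obs = t[obs]
    if np.unique(t_obs).size < 2:
        raise ValueError(
            "observed target values are all one class; logistic imputation "
            "model cannot be fit")
    rng = np.random.default_rng(spec.seed)
    fit = fit_logistic(Z[obs], t_obs, add_intercept=False, max_iter=100, tol=1e-10,
                       ridge=spec.ridge)
    flagged = fit.flagged
    cov = logistic_covariance(Z[obs], fit.coef, add_intercept=False, ridge=spec.ridge) \
        if np.all(np.isfinite(fit.se)) else None
    if cov is not None:
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            L, flagged = None, True
    else:
        L, flagged = None, True
    out = np.tile(t, (spec.M, 1))
    n_mis = int(mis.sum())
    for m in range(spec.M):
        if L is not None:
            beta_star = fit.coef + L @ rng.standard_normal(len(fit.coef))
        else:
            beta_star = fit.coef  # degenerate information: no parameter noise
        if n_mis:
            eta = np.clip(Z[mis] @ beta_star, -700, 700)
            p = 1.0 / (1.0 + np.exp(-eta))
            out[m, mis] = (rng.random(n_mis) < p).astype(float)
    return ImputedData(sample=sample, target_values=out, method="logreg",
                       imputation_flagged=flagged)


_METHODS = {"norm": impute_norm, "pmm": impute_pmm, "logreg": impute_logreg}


def impute(sample: AnalysisSample, spec: ImputationSpec) -> ImputedData:
    """Dispatch to the method named in ``spec``."""
    return _METHODS[spec.method](sample, spec)
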