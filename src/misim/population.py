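"""Super-population generation, calibration, and sampling.

The study design works with a very large synthetic population in which the
truth is known exactly: covariates are drawn from a multivariate normal
(the last five dichotomised at empirical quantiles so their prevalences hit
the configured targets), a binary outcome is simulated from a logistic
model, the analysis model is refit in the full population to obtain the
"true" coefficient vector, and a missing-at-random indicator for the single
target covariate is generated after calibrating the missing-data model's
intercept to the desired missingness prevalence. Analysis samples are then
drawn without replacement, with the target masked where the indicator is 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .glm import fit_logistic
from .params import DGPParams, DGPError, COLUMN_NAMES
from . import rng as _rng


@dataclass
class SuperPopulation:
    """A calibrated population with known truth.

    ``X`` holds the 10 covariates (5 continuous, 5 binary 0/1), ``y`` the
    simulated outcome, ``miss`` the missingness indicator for the target
    variable, ``theta_true`` the logistic MLE of y on X in the full
    population (the estimand of every downstream analysis), and
    ``gamma0_star`` the calibrated missing-data intercept.
    """

    X: np.ndarray
    y: np.ndarray
    miss: np.ndarray
    theta_true: np.ndarray
    gamma0_star: float
    params: DGPParams
    p_missing: float

    @property
    def n_pop(self) -> int:
        return self.X.shape[0]


@dataclass
class AnalysisSample:
    """One without-replacement draw; the target column is NaN where missing."""

    X: np.ndarray              # (n, 10); target column NaN where masked
    y: np.ndarray              # (n,)
    target_index: int
    target_is_binary: bool

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of rows with the target observed."""
        return ~np.isnan(self.X[:, self.target_index])

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.X[:, self.target_index]).sum())


def generate_covariates(params: DGPParams, seed: int) -> np.ndarray:
    """Draw the latent MVN and dichotomise the last five columns.

    Thresholds are the empirical (1 - prevalence) quantiles of each realised
    latent column, so the sample prevalence of the 1-coded level matches the
    configured target by construction.
    """
    gen = _rng.child_rng(seed, _rng.POPULATION)
    try:
        chol = np.linalg.cholesky(params.sigma)
    except np.linalg.LinAlgError as err:
        raise DGPError(
            f"sigma is not positive definite; Cholesky failed: {params.sigma!r}") from err
    Z = gen.standard_normal((params.n_pop, 10))
    X = params.mu + Z @ chol.T
    for k, pi in enumerate(params.binary_prevalences):
        col = 5 + k
        thresh = np.quantile(X[:, col], 1.0 - pi)
        X[:, col] = (X[:, col] > thresh).astype(float)
    return X


def calibrate_logistic_intercept(eta_partial: np.ndarray, p_target: float,
                                 tol: float = 1e-4, bracket: float = 30.0) -> float:
    """Intercept g0 with mean(expit(g0 + eta_partial)) within tol of p_target.

    Monotone bisection on [-bracket, bracket]; the mean probability is
    strictly increasing in the intercept, so bisection always converges.
    """
    if not 0.0 < p_target < 1.0:
        raise DGPError(f"target proportion must lie in (0, 1), got {p_target}")
    eta = np.asarray(eta_partial, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise DGPError("non-finite linear predictor in intercept calibration")

    def mean_p(g0: float) -> float:
        return float(expit(g0 + eta).mean())

    lo, hi = -bracket, bracket
    if mean_p(lo) > p_target or mean_p(hi) < p_target:
        raise DGPError(
            "slopes produce degenerate probabilities; cannot reach target proportion "
            f"{p_target} within intercept bracket +/-{bracket}")
    while True:
        mid = 0.5 * (lo + hi)
        pm = mean_p(mid)
        if abs(pm - p_target) <= tol or (hi - lo) < 1e-13:
            return mid
        if pm < p_target:
            lo = mid
        else:
            hi = mid


def simulate_outcomes(X: np.ndarray, outcome_coefs: np.ndarray, seed: int) -> np.ndarray:
    """Bernoulli outcome with subject-specific probability expit(b0 + X @ b)."""
    outcome_coefs = np.asarray(outcome_coefs, dtype=float)
    if outcome_coefs.shape[0] != X.shape[1] + 1:
        raise DGPError(
            f"outcome_coefs length {outcome_coefs.shape[0]} does not match "
            f"1 + {X.shape[1]} covariates")
    eta = outcome_coefs[0] + X @ outcome_coefs[1:]
    if not np.all(np.isfinite(eta)):
        raise DGPError("non-finite linear predictor in outcome simulation")
    gen = _rng.child_rng(seed, _rng.OUTCOME)
    return (gen.random(X.shape[0]) < expit(eta)).astype(float)


def fit_true_coefficients(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Population logistic MLE of y on the 10 covariates; the estimand."""
    fit = fit_logistic(X, y, max_iter=100, tol=1e-10)
    if fit.flagged:
        raise DGPError(
            "population-scale logistic fit failed to converge; the DGP is broken "
            f"(iterations={fit.n_iter}, converged={fit.converged})")
    return fit.coef


def missingness_linear_predictor(X: np.ndarray, y: np.ndarray,
                                 params: DGPParams) -> np.ndarray:
    """Slope part of the missing-data model: 9 non-target covariates + outcome.

    The target column is never read — missingness is MAR by construction.
    """
    idx = params.missingness_predictor_indices
    Z = np.column_stack([X[:, idx], y])
    return Z @ params.missingness_coefs


def calibrate_missingness_intercept(X: np.ndarray, y: np.ndarray, params: DGPParams,
                                    p_missing: float, tol: float = 1e-4) -> float:
    """Intercept making the population-mean missingness probability hit p_missing."""
    eta = missingness_linear_predictor(X, y, params)
    try:
        return calibrate_logistic_intercept(eta, p_missing, tol=tol)
    except DGPError as err:
        raise DGPError(
            f"missingness calibration failed for coefficients "
            f"{params.missingness_coefs!r}: {err}") from err


def assign_missingness(X: np.ndarray, y: np.ndarray, params: DGPParams,
                       gamma0_star: float, seed: int) -> np.ndarray:
    """Bernoulli missingness indicator from the calibrated MAR model."""
    eta = gamma0_star + missingness_linear_predictor(X, y, params)
    gen = _rng.child_rng(seed, _rng.MISSINGNESS)
    return (gen.random(X.shape[0]) < expit(eta)).astype(float)


def build_super_population(params: DGPParams, p_missing: float, seed: int,
                           calib_tol: float = 1e-4) -> SuperPopulation:
    """Generate and calibrate the full population for one missingness prevalence.

    Steps: covariates -> (optional) outcome-intercept calibration to the
    configured event rate -> outcome draw -> "true"-coefficient refit ->
    missing-data-intercept calibration -> missingness draw.
    """
    X = generate_covariates(params, seed)
    coefs = params.outcome_coefs.copy()
    if params.event_rate is not None:
        coefs[0] = calibrate_logistic_intercept(X @ coefs[1:], params.event_rate,
                                                tol=calib_tol)
    y = simulate_outcomes(X, coefs, seed)
    theta_true = fit_true_coefficients(X, y)
    gamma0 = calibrate_missingness_intercept(X, y, params, p_missing, tol=calib_tol)
    miss = assign_missingness(X, y, params, gamma0, seed)
    return SuperPopulation(X=X, y=y, miss=miss, theta_true=theta_true,
                           gamma0_star=gamma0, params=params, p_missing=p_missing)


def draw_sample(pop: SuperPopulation, n_sample: int, seed, *,
                replicate: int = 0) -> AnalysisSample:
    """Sample ``n_sample`` rows without replacement and mask the target.

    ``seed`` may be an integer (a replicate stream is derived from it and
    ``replicate``) or an already-constructed ``numpy.random.Generator``.
    """
    if n_sample > pop.n_pop:
        raise ValueError(f"n_sample={n_sample} exceeds population size {pop.n_pop}")
    if isinstance(seed, np.random.Generator):
        gen = seed
    else:
        gen = _rng.child_rng(seed, _rng.REPLICATE, replicate)
    rows = gen.choice(pop.n_pop, size=n_sample, replace=False)
    X = pop.X[rows].copy()
    y = pop.y[rows].copy()
    j = pop.params.target_index
    X[pop.miss[rows] == 1, j] = np.nan
    return AnalysisSample(X=X, y=y, target_index=j,
                          target_is_binary=pop.params.target_variable == "smoker")


def model_diagnostics(y: np.ndarray, p_hat: np.ndarray,
                      r2_index: str = "cox-snell") -> tuple[float, float]:
    """Discrimination and explained-variation summaries of a binary-risk model.

    Returns the c-statistic (probability that a random event subject has a
    higher predicted risk than a random non-event subject, ties counting
    one half) and a generalized R-squared from the likelihood ratio of the
    model against the intercept-only model: Cox-Snell ``1 - exp(-LR/n)``,
    or its Nagelkerke rescaling when ``r2_index="nagelkerke"``.
    """
    y = np.asarray(y, dtype=float).ravel()
    p_hat = np.asarray(p_hat, dtype=float).ravel()
    if np.unique(y).size < 2:
        raise ValueError("y must contain both classes")
    from scipy.stats import rankdata
    n1 = int(y.sum())
    n0 = y.size - n1
    ranks = rankdata(p_hat)            # midranks handle ties (count 1/2)
    c = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    with np.errstate(divide="ignore"):
        ll_model = float(np.sum(y * np.log(p_hat) + (1 - y) * np.log1p(-p_hat)))
    pbar = y.mean()
    ll_null = float(y.size * (pbar * np.log(pbar) + (1 - pbar) * np.log1p(-pbar)))
    n = y.size
    r2_cs = 1.0 - np.exp(-2.0 * (ll_model - ll_null) / n)
    if r2_index == "cox-snell":
        r2 = r2_cs
    elif r2_index == "nagelkerke":
        r2 = r2_cs / (1.0 - np.exp(2.0 * ll_null / n))
    else:
        raise ValueError(f"unknown r2_index {r2_index!r}")
    return float(c), float(r2)
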