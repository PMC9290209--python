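"""Data-generating-process parameters.

The synthetic population mimics a registry of patients hospitalised for
acute myocardial infarction: five continuous baseline covariates (age,
systolic blood pressure, heart rate, hemoglobin, cholesterol), five binary
covariates obtained by dichotomising latent normals (female sex, angina,
diabetes, previous AMI, current smoker), and a binary one-year mortality
outcome generated from a logistic model. A single covariate (cholesterol,
or current smoker) is subject to missingness; its missing-at-random model
depends on the other nine covariates and the outcome, never on the target
itself — that dependence is excluded structurally: the coefficient vector
has no slot for the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

CONTINUOUS_NAMES = ("age", "sbp", "heart_rate", "hemoglobin", "cholesterol")
BINARY_NAMES = ("female", "angina", "diabetes", "prev_ami", "smoker")
COLUMN_NAMES = CONTINUOUS_NAMES + BINARY_NAMES

#: variables that may be set missing, with their column index
TARGETS = {"cholesterol": 4, "smoker": 9}


class DGPError(ValueError):
    """Raised when DGP parameters violate their invariants."""


@dataclass(frozen=True)
class DGPParams:
    """Every free constant of the data-generating process.

    Parameters
    ----------
    mu : (10,) array
        Mean of the latent multivariate-normal covariates.
    sigma : (10, 10) array
        Covariance of the latent covariates; must be symmetric positive
        definite.
    binary_prevalences : (5,) array
        Target prevalences for the five dichotomised covariates, each
        strictly inside (0, 1). Dichotomisation thresholds are the
        empirical (1 - prevalence) quantiles of the realised latent
        columns, so sample prevalence matches by construction.
    outcome_coefs : (11,) array
        Intercept + 10 slopes of the outcome logistic model, log-odds
        scale. When ``event_rate`` is set the intercept is recalibrated
        on the realised covariates so the population mean event
        probability hits the target.
    missingness_coefs : (10,) array
        Slopes of the missing-data model: the nine covariates other than
        the target (in column order, target removed) followed by the
        outcome. The intercept is always calibrated at run time to the
        scenario's missingness prevalence.
    target_variable : str
        ``"cholesterol"`` (continuous, column 4) or ``"smoker"``
        (binary, column 9).
    n_pop : int
        Super-population size.
    event_rate : float or None
        Target marginal outcome prevalence; ``None`` keeps the shipped
        intercept as-is.
    """

    mu: np.ndarray
    sigma: np.ndarray
    binary_prevalences: np.ndarray
    outcome_coefs: np.ndarray
    missingness_coefs: np.ndarray
    target_variable: str = "cholesterol"
    n_pop: int = 1_000_000
    event_rate: float | None = 0.201

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        object.__setattr__(self, "binary_prevalences",
                           np.asarray(self.binary_prevalences, dtype=float))
        object.__setattr__(self, "outcome_coefs",
                           np.asarray(self.outcome_coefs, dtype=float))
        object.__setattr__(self, "missingness_coefs",
                           np.asarray(self.missingness_coefs, dtype=float))
        self.validate()

    def validate(self) -> None:
        if self.mu.shape != (10,):
            raise DGPError(f"mu must have length 10, got shape {self.mu.shape}")
        if self.sigma.shape != (10, 10):
            raise DGPError(f"sigma must be 10x10, got shape {self.sigma.shape}")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise DGPError("sigma is not symmetric")
        eigmin = float(np.linalg.eigvalsh(self.sigma).min())
        if eigmin <= 0:
            raise DGPError(
                f"sigma is not positive definite (smallest eigenvalue {eigmin:.3e})")
        if self.binary_prevalences.shape != (5,):
            raise DGPError("binary_prevalences must have length 5")
        if not np.all((self.binary_prevalences > 0) & (self.binary_prevalences < 1)):
            raise DGPError("each binary prevalence must lie strictly inside (0, 1)")
        if self.outcome_coefs.shape != (11,):
            raise DGPError("outcome_coefs must have length 11 (intercept + 10 slopes)")
        if self.missingness_coefs.shape != (10,):
            raise DGPError(
                "missingness_coefs must have length 10 (9 non-target covariates + outcome); "
                "the target variable has no coefficient slot (MAR by construction)")
        if self.target_variable not in TARGETS:
            raise DGPError(
                f"target_variable must be one of {sorted(TARGETS)}, got {self.target_variable!r}")
        if self.n_pop <= 0:
            raise DGPError("n_pop must be positive")
        if self.event_rate is not None and not 0 < self.event_rate < 1:
            raise DGPError("event_rate must lie in (0, 1)")

    @property
    def target_index(self) -> int:
        return TARGETS[self.target_variable]

    @property
    def missingness_predictor_indices(self) -> np.ndarray:
        """Column indices of the nine covariates entering the missing-data model."""
        return np.array([j for j in range(10) if j != self.target_index])

    def with_target(self, target_variable: str, missingness_coefs=None) -> "DGPParams":
        kwargs = {"target_variable": target_variable}
        if missingness_coefs is not None:
            kwargs["missingness_coefs"] = np.asarray(missingness_coefs, dtype=float)
        return replace(self, **kwargs)
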