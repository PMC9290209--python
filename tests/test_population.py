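"""Super-population generation, calibration, and sampling."""

import numpy as np
import pytest
from scipy.special import expit, logit

import misim
from misim.params import DGPParams, DGPError
from misim.population import (
    calibrate_logistic_intercept,
    missingness_linear_predictor,
)


def _plain_params(n_pop=50_000, **kw):
    base = dict(
        mu=np.zeros(10), sigma=np.eye(10),
        binary_prevalences=np.full(5, 0.5),
        outcome_coefs=np.zeros(11),
        missingness_coefs=np.zeros(10),
        target_variable="cholesterol", n_pop=n_pop, event_rate=None)
    base.update(kw)
    return DGPParams(**base)


class TestGenerateCovariates:
    def test_identity_sigma_gives_half_prevalence_and_no_correlation(self):
        X = misim.generate_covariates(_plain_params(n_pop=200_000), seed=1)
        assert np.allclose(X[:, 5:].mean(axis=0), 0.5)  # empirical quantile: exact
        corr = np.corrcoef(X[:, :5], rowvar=False)
        assert np.all(np.abs(corr - np.eye(5)) < 0.01)

    def test_binary_columns_are_zero_one(self):
        X = misim.generate_covariates(_plain_params(n_pop=1000), seed=2)
        assert set(np.unique(X[:, 5:])) == {0.0, 1.0}

    def test_sample_correlation_matches_generating_value(self):
        sigma = np.eye(10)
        sigma[0, 1] = sigma[1, 0] = 0.4
        X = misim.generate_covariates(
            _plain_params(n_pop=400_000, sigma=sigma), seed=3)
        r = np.corrcoef(X[:, 0], X[:, 1])[0, 1]
        assert r == pytest.approx(0.4, abs=0.01)

    def test_default_prevalences_hit_targets(self):
        params = misim.default_params("cholesterol", n_pop=300_000)
        X = misim.generate_covariates(params, seed=4)
        np.testing.assert_allclose(
            X[:, 5:].mean(axis=0), [0.36, 0.32, 0.27, 0.24, 0.33], atol=0.002)

    def test_non_positive_definite_sigma_rejected(self):
        sigma = np.eye(10)
        sigma[0, 0] = -1.0
        with pytest.raises(DGPError, match="positive definite"):
            _plain_params(sigma=sigma)


class TestSimulateOutcomes:
    def test_zero_coefficients_give_half_prevalence(self):
        params = _plain_params(n_pop=200_000)
        X = misim.generate_covariates(params, seed=5)
        y = misim.simulate_outcomes(X, np.zeros(11), seed=5)
        assert y.mean() == pytest.approx(0.5, abs=0.005)

    def test_extreme_linear_predictors_are_deterministic(self):
        X = np.array([[-50.0], [0.0], [0.0], [50.0]])
        y = misim.simulate_outcomes(X, np.array([0.0, 1.0]), seed=6)
        assert y[0] == 0.0 and y[3] == 1.0
        assert set(y[1:3]) <= {0.0, 1.0}

    def test_coefficient_length_checked(self):
        with pytest.raises(DGPError, match="does not match"):
            misim.simulate_outcomes(np.zeros((5, 10)), np.zeros(5), seed=0)


class TestFitTrueCoefficients:
    def test_recovers_generating_coefficients(self):
        params = _plain_params(n_pop=150_000)
        X = misim.generate_covariates(params, seed=7)
        coefs = np.array([-1.0, 0.3, -0.2, 0.1, 0.0, -0.25,
                          0.2, 0.1, 0.4, 0.3, -0.2])
        y = misim.simulate_outcomes(X, coefs, seed=7)
        fitted = misim.fit_true_coefficients(X, y)
        # binary cols are thresholded latents, so compare slope by slope
        np.testing.assert_allclose(fitted, coefs, atol=0.05)

    def test_refit_is_bit_identical(self):
        params = _plain_params(n_pop=20_000)
        X = misim.generate_covariates(params, seed=8)
        y = misim.simulate_outcomes(X, np.zeros(11), seed=8)
        assert np.array_equal(misim.fit_true_coefficients(X, y),
                              misim.fit_true_coefficients(X, y))


class TestInterceptCalibration:
    def test_zero_slopes_closed_form(self):
        eta = np.zeros(10_000)
        assert calibrate_logistic_intercept(eta, 0.3) == pytest.approx(
            logit(0.3), abs=1e-3)
        assert calibrate_logistic_intercept(eta, 0.5) == pytest.approx(0.0, abs=1e-3)

    def test_mean_probability_hits_target(self):
        gen = np.random.default_rng(9)
        eta = gen.standard_normal(100_000)
        for target in (0.05, 0.5, 0.95):
            g0 = calibrate_logistic_intercept(eta, target, tol=1e-4)
            assert expit(g0 + eta).mean() == pytest.approx(target, abs=1e-4)

    def test_monotone_in_intercept(self):
        gen = np.random.default_rng(10)
        eta = gen.standard_normal(10_000)
        probs = [expit(g + eta).mean() for g in np.linspace(-5, 5, 21)]
        assert np.all(np.diff(probs) > 0)

    def test_degenerate_target_rejected(self):
        with pytest.raises(DGPError, match="target proportion"):
            calibrate_logistic_intercept(np.zeros(10), 1.2)


class TestMissingness:
    def test_realized_proportion_matches_target(self):
        params = misim.default_params("cholesterol", n_pop=200_000)
        pop = misim.build_super_population(params, 0.05, seed=11)
        assert pop.miss.mean() == pytest.approx(0.05, abs=0.002)

    def test_mcar_special_case_has_no_covariate_structure(self):
        params = _plain_params(n_pop=100_000)
        pop = misim.build_super_population(params, 0.5, seed=12)
        fit = misim.fit_true_coefficients(pop.X, pop.miss)
        assert np.all(np.abs(fit[1:]) < 0.05)

    def test_target_column_is_never_read(self):
        # MAR by construction: the linear predictor is computable with the
        # target column destroyed
        params = misim.default_params("cholesterol", n_pop=5_000)
        pop = misim.build_super_population(params, 0.3, seed=13)
        X = pop.X.copy()
        X[:, params.target_index] = np.nan
        eta = missingness_linear_predictor(X, pop.y, params)
        assert np.all(np.isfinite(eta))


class TestDrawSample:
    def test_full_population_is_a_permutation(self, benign_pop):
        s = misim.draw_sample(benign_pop, benign_pop.n_pop, seed=14)
        assert s.n == benign_pop.n_pop
        np.testing.assert_allclose(np.sort(s.y), np.sort(benign_pop.y))

    def test_oversampling_rejected(self, benign_pop):
        with pytest.raises(ValueError, match="exceeds population"):
            misim.draw_sample(benign_pop, benign_pop.n_pop + 1, seed=15)

    def test_missing_fraction_matches_population_rate(self, benign_pop):
        fracs = [misim.draw_sample(benign_pop, 1000, seed=16, replicate=r).n_missing / 1000
                 for r in range(200)]
        assert np.mean(fracs) == pytest.approx(benign_pop.miss.mean(), abs=0.01)

    def test_nonmissing_columns_complete(self, benign_pop):
        s = misim.draw_sample(benign_pop, 500, seed=17)
        other = [j for j in range(10) if j != s.target_index]
        assert np.all(np.isfinite(s.X[:, other]))


class TestModelDiagnostics:
    def test_brute_force_concordance(self):
        # y=(1,1,0,0), p=(0.8,0.6,0.7,0.2): pairs (.8,.7) (.8,.2) (.6,.2)
        # concordant, (.6,.7) discordant, no ties -> c = 3/4
        c, _ = misim.model_diagnostics(np.array([1, 1, 0, 0.0]),
                                       np.array([0.8, 0.6, 0.7, 0.2]))
        assert c == pytest.approx(3.0 / 4)

    def test_half_credit_for_ties(self):
        c, _ = misim.model_diagnostics(np.array([1.0, 0.0]), np.array([0.4, 0.4]))
        assert c == pytest.approx(0.5)

    def test_perfect_and_null_discrimination(self):
        y = np.array([0, 0, 1, 1.0])
        c, _ = misim.model_diagnostics(y, np.array([0.1, 0.2, 0.8, 0.9]))
        assert c == 1.0
        c, r2 = misim.model_diagnostics(y, np.full(4, 0.5))
        assert c == 0.5
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_concordance_matches_sklearn_auc(self, rng):
        from sklearn.metrics import roc_auc_score
        y = (rng.random(500) < 0.3).astype(float)
        p = rng.random(500)
        c, _ = misim.model_diagnostics(y, p)
        assert c == pytest.approx(roc_auc_score(y, p), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            misim.model_diagnostics(np.zeros(5), np.full(5, 0.2))


def test_default_missingness_models_discriminate_as_documented():
    """The shipped missing-data models, at the registry missingness rates,
    have c ~ 0.67 (cholesterol) / 0.71 (smoker) and Nagelkerke R2 ~ 0.12 / 0.11."""
    from misim.defaults import DIAGNOSTIC_PREVALENCES
    for target, c_doc, r2_doc in [("cholesterol", 0.67, 0.12), ("smoker", 0.71, 0.11)]:
        params = misim.default_params(target, n_pop=150_000)
        pop = misim.build_super_population(
            params, DIAGNOSTIC_PREVALENCES[target], seed=18)
        eta = pop.gamma0_star + missingness_linear_predictor(pop.X, pop.y, params)
        c, r2 = misim.model_diagnostics(pop.miss, expit(eta), r2_index="nagelkerke")
        assert c == pytest.approx(c_doc, abs=0.02)
        assert r2 == pytest.approx(r2_doc, abs=0.03)
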