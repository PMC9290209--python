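"""The three univariate imputation methods and the M-selection rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import misim
from misim.impute import ImputationSpec, impute_norm, impute_pmm, impute_logreg
from conftest import make_sample


class TestChooseM:
    @pytest.mark.parametrize("p,expected", [(0.80, 80), (0.95, 95), (0.01, 2),
                                            (0.25, 25), (0.05, 5), (0.024, 2)])
    def test_rule_examples(self, p, expected):
        assert misim.choose_M(p) == expected

    @given(st.floats(min_value=0.001, max_value=0.999))
    @settings(deadline=None)
    def test_percentage_rule_with_floor(self, p):
        m = misim.choose_M(p)
        assert m >= 2
        assert m == max(2, int(np.floor(100 * p + 0.5)))

    def test_domain(self):
        with pytest.raises(ValueError):
            misim.choose_M(0.0)
        with pytest.raises(ValueError):
            misim.choose_M(1.0)


class TestNorm:
    def test_zero_missing_gives_identical_copies(self):
        s = make_sample(n=200, n_missing=0, seed=1)
        imp = impute_norm(s, ImputationSpec("norm", M=3, seed=1))
        for m in range(3):
            np.testing.assert_array_equal(imp.target_values[m], s.X[:, 4])

    def test_observed_values_untouched_and_draws_differ(self):
        s = make_sample(n=300, n_missing=80, seed=2)
        imp = impute_norm(s, ImputationSpec("norm", M=2, seed=2))
        obs = s.observed
        for m in range(2):
            np.testing.assert_array_equal(imp.target_values[m][obs], s.X[obs, 4])
        assert not np.array_equal(imp.target_values[0][~obs],
                                  imp.target_values[1][~obs])

    def test_rank_deficient_predictors_rejected(self):
        s = make_sample(n=100, n_missing=20, seed=3)
        s.X[:, 0] = s.X[:, 1]  # collinear pair among predictors
        with pytest.raises(ValueError, match="rank deficient"):
            impute_norm(s, ImputationSpec("norm", M=2, seed=3))

    def test_too_few_observed_rows_rejected(self):
        s = make_sample(n=30, n_missing=25, seed=4)
        with pytest.raises(ValueError, match="at least"):
            impute_norm(s, ImputationSpec("norm", M=2, seed=4))

    def test_unbiased_under_correct_model(self):
        """Parameter-recovery oracle: with the target exactly linear in the
        predictors and MCAR missingness, the pooled analysis coefficient of
        the target is unbiased within 3 Monte Carlo SEs."""
        from misim.pooling import pool_analysis
        reps = 120
        ests = np.empty(reps)
        truth = 0.3    # the y-model slope on the target in make_sample
        for r in range(reps):
            s = make_sample(n=1000, n_missing=500, seed=1000 + r)
            imp = impute_norm(s, ImputationSpec("norm", M=10, seed=2000 + r))
            pooled = pool_analysis(imp)
            ests[r] = pooled.estimate[1 + s.target_index]
        mc_se = ests.std(ddof=1) / np.sqrt(reps)
        assert abs(ests.mean() - truth) < 3 * mc_se + 0.01


class TestPMM:
    def test_imputed_values_come_from_observed_multiset(self):
        s = make_sample(n=400, n_missing=150, seed=5)
        imp = impute_pmm(s, ImputationSpec("pmm", M=5, donor_pool_k=5, seed=5))
        observed_values = set(s.X[s.observed, 4])
        for m in range(5):
            assert set(imp.target_values[m][~s.observed]) <= observed_values

    def test_nearest_five_toy(self):
        """Donor predictions {1.0, 2.0, 9.0, 9.5, 9.9, 10.0}, recipient at
        1.2, k=5: the pool is the five nearest, i.e. 10.0 is excluded."""
        from misim.impute import _nearest_donors
        rng = np.random.default_rng(0)
        donors = np.array([1.0, 2.0, 9.0, 9.5, 9.9, 10.0])
        pool = _nearest_donors(np.array([1.2]), donors, 5, rng)
        assert set(donors[pool[0]]) == {1.0, 2.0, 9.0, 9.5, 9.9}

    def test_tie_break_is_uniform(self):
        from misim.impute import _nearest_donors
        rng = np.random.default_rng(1)
        donors = np.zeros(6)   # all equidistant
        counts = np.zeros(6)
        for _ in range(600):
            pool = _nearest_donors(np.array([1.0]), donors, 1, rng)
            counts[pool[0, 0]] += 1
        assert counts.min() > 50   # each donor drawn roughly 100 times

    def test_donor_pool_cannot_exceed_donors(self):
        s = make_sample(n=60, n_missing=30, seed=6)
        with pytest.raises(ValueError, match="donor_pool_k"):
            impute_pmm(s, ImputationSpec("pmm", M=2, donor_pool_k=31, seed=6))

    def test_full_pool_limit_draws_any_donor(self):
        s = make_sample(n=80, n_missing=20, seed=7)
        k = int(s.observed.sum())
        imp = impute_pmm(s, ImputationSpec("pmm", M=3, donor_pool_k=k, seed=7))
        observed_values = set(s.X[s.observed, 4])
        assert set(imp.target_values[0][~s.observed]) <= observed_values


class TestLogreg:
    def test_values_are_binary_and_observed_untouched(self):
        s = make_sample(n=500, n_missing=150, target_is_binary=True, seed=8)
        imp = impute_logreg(s, ImputationSpec("logreg", M=4, seed=8))
        for m in range(4):
            assert set(np.unique(imp.target_values[m])) <= {0.0, 1.0}
            np.testing.assert_array_equal(
                imp.target_values[m][s.observed], s.X[s.observed, 9])

    def test_zero_missing_gives_identical_copies(self):
        s = make_sample(n=200, n_missing=0, target_is_binary=True, seed=9)
        imp = impute_logreg(s, ImputationSpec("logreg", M=3, seed=9))
        for m in range(3):
            np.testing.assert_array_equal(imp.target_values[m], s.X[:, 9])

    def test_one_class_observed_rejected(self):
        s = make_sample(n=100, n_missing=30, target_is_binary=True, seed=10)
        s.X[s.observed, 9] = 1.0
        with pytest.raises(ValueError, match="one class"):
            impute_logreg(s, ImputationSpec("logreg", M=2, seed=10))

    def test_recovers_conditional_prevalence(self):
        """Recovery oracle: mean imputed prevalence tracks the true
        conditional prevalence of the missing rows under MCAR."""
        reps = 60
        diffs = np.empty(reps)
        for r in range(reps):
            s = make_sample(n=1500, n_missing=450, target_is_binary=True,
                            seed=3000 + r)
            imp = impute_logreg(s, ImputationSpec("logreg", M=5, seed=4000 + r))
            imputed_prev = imp.target_values[:, ~s.observed].mean()
            # MCAR: observed prevalence estimates the missing rows' prevalence
            diffs[r] = imputed_prev - s.X[s.observed, 9].mean()
        mc_se = diffs.std(ddof=1) / np.sqrt(reps)
        assert abs(diffs.mean()) < 3 * mc_se + 0.005


def test_imputation_is_seed_reproducible():
    s = make_sample(n=300, n_missing=100, seed=11)
    a = impute_norm(s, ImputationSpec("norm", M=3, seed=99))
    b = impute_norm(s, ImputationSpec("norm", M=3, seed=99))
    np.testing.assert_array_equal(a.target_values, b.target_values)
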