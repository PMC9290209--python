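import numpy as np
import pytest

import misim

SEED = 20220718


@pytest.fixture(scope="session")
def benign_pop():
    """Desk-scale default population, continuous target, 25% missingness."""
    params = misim.default_params("cholesterol", n_pop=100_000)
    return misim.build_super_population(params, 0.25, seed=SEED)


@pytest.fixture(scope="session")
def benign_metrics(benign_pop):
    """Performance metrics for the benign scenario: n=1,000, 25% missing,
    parametric imputation, M=25, 250 replicates."""
    scenario = misim.Scenario(1000, 0.25, "norm", n_reps=250)
    records = misim.run_scenario(scenario, benign_pop, SEED)
    return misim.summarize(misim.records_to_frame(records))


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)


def make_sample(n=400, n_missing=100, target_is_binary=False, seed=0,
                beta=None, sigma=1.0):
    """A hand-built AnalysisSample: 10 covariates, the target (column 4 or 9)
    exactly linear (or logistic) in the others, MCAR missingness."""
    gen = np.random.default_rng(seed)
    X = gen.standard_normal((n, 10))
    j = 9 if target_is_binary else 4
    others = [k for k in range(10) if k != j]
    if beta is None:
        beta = np.linspace(0.2, -0.2, 9)
    lin = X[:, others] @ beta
    if target_is_binary:
        X[:, j] = (gen.random(n) < 1 / (1 + np.exp(-lin))).astype(float)
        for k in range(5, 9):
            X[:, k] = (X[:, k] > 0).astype(float)
    else:
        X[:, j] = lin + sigma * gen.standard_normal(n)
    y = (gen.random(n) < 1 / (1 + np.exp(-(0.3 * X[:, j] - 0.5)))).astype(float)
    mask = gen.choice(n, size=n_missing, replace=False)
    X[mask, j] = np.nan
    return misim.AnalysisSample(X=X, y=y, target_index=j,
                                target_is_binary=target_is_binary)
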