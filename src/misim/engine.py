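"""Scenario grid and replicate loop.

One super-population is built per (target variable, missingness prevalence)
pair and reused across sample sizes and replicates. Every number emitted is
a deterministic function of (master seed, scenario, replicate index): each
replicate derives two private streams — one for the without-replacement
sample draw, one for the imputation — from the master seed and the
scenario's integer key, so replicates can be re-run in isolation and in any
order (including in parallel) without changing the results.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .impute import ImputationSpec, choose_M, impute
from .params import COLUMN_NAMES
from .pooling import pool_analysis
from .population import SuperPopulation, draw_sample
from . import rng as _rng

TERM_NAMES = ("intercept",) + COLUMN_NAMES

_METHOD_CODE = {"norm": 0, "pmm": 1, "logreg": 2}
_TARGET_CODE = {"cholesterol": 0, "smoker": 1}

#: methods valid for each missingness target
_VALID = {"cholesterol": ("norm", "pmm"), "smoker": ("logreg",)}


@dataclass(frozen=True)
class Scenario:
    n_sample: int
    p_missing: float
    method: str
    target_variable: str = "cholesterol"
    n_reps: int = 1000
    M: int | None = None            # None: the choose_M rule
    donor_pool_k: int = 5
    ridge: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_missing < 1.0:
            raise ValueError(f"p_missing must lie in (0, 1), got {self.p_missing}")
        if self.n_sample < 1:
            raise ValueError("n_sample must be positive")
        if self.method not in _METHOD_CODE:
            raise ValueError(f"unknown method {self.method!r}")
        if self.method not in _VALID[self.target_variable]:
            raise ValueError(
                f"method {self.method!r} is not valid for target "
                f"{self.target_variable!r}: continuous cholesterol takes norm/pmm, "
                "binary smoker takes logreg")

    @property
    def scenario_id(self) -> str:
        return (f"{self.target_variable}-{self.method}"
                f"-n{self.n_sample}-p{int(round(100 * self.p_missing)):02d}")

    @property
    def key(self) -> tuple[int, ...]:
        """Integer key feeding the replicate seed streams."""
        return (self.n_sample, int(round(100 * self.p_missing)),
                _METHOD_CODE[self.method], _TARGET_CODE[self.target_variable])

    @property
    def n_imputations(self) -> int:
        return self.M if self.M is not None else choose_M(self.p_missing)


@dataclass
class ReplicateRecord:
    scenario_id: str
    replicate: int
    M: int
    estimate: np.ndarray            # (11,)
    se: np.ndarray
    df: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    covered: np.ndarray             # bool (11,), CI contains theta_true
    truth: np.ndarray
    n_flagged_fits: int = 0
    error: str | None = None


def _failed_record(scenario: Scenario, r: int, truth: np.ndarray,
                   reason: str) -> ReplicateRecord:
    nan = np.full(len(TERM_NAMES), np.nan)
    return ReplicateRecord(
        scenario_id=scenario.scenario_id, replicate=r, M=scenario.n_imputations,
        estimate=nan, se=nan.copy(), df=nan.copy(), ci_lo=nan.copy(),
        ci_hi=nan.copy(), covered=np.zeros(len(TERM_NAMES), dtype=bool),
        truth=truth, n_flagged_fits=0, error=reason)


def run_replicate(scenario: Scenario, pop: SuperPopulation, master_seed: int,
                  replicate: int) -> ReplicateRecord:
    """One sample -> impute -> fit M models -> pool -> Barnard-Rubin CIs."""
    key = scenario.key
    draw_rng = _rng.child_rng(master_seed, _rng.REPLICATE, *key, replicate, 0)
    imp_seed = np.random.SeedSequence(
        [master_seed, _rng.REPLICATE, *key, replicate, 1])
    truth = pop.theta_true
    try:
        sample = draw_sample(pop, scenario.n_sample, draw_rng)
        spec = ImputationSpec(method=scenario.method, M=scenario.n_imputations,
                              donor_pool_k=scenario.donor_pool_k, seed=imp_seed,
                              ridge=scenario.ridge)
        imputed = impute(sample, spec)
        pooled = pool_analysis(imputed, ridge=scenario.ridge)
    except (ValueError, np.linalg.LinAlgError) as err:
        return _failed_record(scenario, replicate, truth, str(err))
    covered = (pooled.ci_lo <= truth) & (truth <= pooled.ci_hi)
    return ReplicateRecord(
        scenario_id=scenario.scenario_id, replicate=replicate, M=pooled.M,
        estimate=pooled.estimate, se=pooled.se, df=pooled.df,
        ci_lo=pooled.ci_lo, ci_hi=pooled.ci_hi, covered=covered, truth=truth,
        n_flagged_fits=pooled.n_flagged_fits, error=None)


def run_scenario(scenario: Scenario, pop: SuperPopulation, master_seed: int,
                 *, n_jobs: int = 1, progress: bool = False) -> list[ReplicateRecord]:
    """All replicates of one scenario; order is by replicate index regardless
    of execution order, so serial and parallel runs emit identical output."""
    if abs(pop.p_missing - scenario.p_missing) > 1e-12:
        raise ValueError(
            f"population calibrated for p_missing={pop.p_missing}, scenario "
            f"asks for {scenario.p_missing}")
    reps = range(scenario.n_reps)
    if n_jobs == 1:
        records = [run_replicate(scenario, pop, master_seed, r) for r in reps]
    else:
        from joblib import Parallel, delayed
        records = Parallel(n_jobs=n_jobs)(
            delayed(run_replicate)(scenario, pop, master_seed, r) for r in reps)
    if progress:
        n_flag = sum(r.n_flagged_fits > 0 for r in records)
        n_err = sum(r.error is not None for r in records)
        print(f"[misim] {scenario.scenario_id}: {scenario.n_reps} replicates, "
              f"{n_flag} with flagged fits, {n_err} failed", file=sys.stderr)
    return records


def _p_grid(step: float) -> list[float]:
    return [round(p, 2) for p in np.arange(0.05, 0.951, step)]


def default_grid(n_reps: int = 1000) -> list[Scenario]:
    """The full study grid: three method arms over five sample sizes.

    Sample sizes 500-10,000 sweep missingness 0.05-0.95 in steps of 0.05;
    n = 25,000 uses steps of 0.10 (computational burden at that size).
    """
    arms = [("cholesterol", "norm"), ("cholesterol", "pmm"), ("smoker", "logreg")]
    grid = []
    for target, method in arms:
        for n in (500, 1000, 5000, 10000):
            for p in _p_grid(0.05):
                grid.append(Scenario(n, p, method, target, n_reps=n_reps))
        for p in _p_grid(0.10):
            grid.append(Scenario(25000, p, method, target, n_reps=n_reps))
    return grid


def desk_grid(n_reps: int = 250) -> list[Scenario]:
    """A small profile for a single workstation: two sample sizes, four
    missingness levels per arm. The full grid is the cluster profile."""
    arms = [("cholesterol", "norm"), ("cholesterol", "pmm"), ("smoker", "logreg")]
    return [Scenario(n, p, method, target, n_reps=n_reps)
            for target, method in arms
            for n in (500, 1000)
            for p in (0.25, 0.5, 0.9, 0.95)]


def records_to_frame(records: list[ReplicateRecord]) -> pd.DataFrame:
    """Long-format frame: one row per (replicate, model term)."""
    rows = []
    for rec in records:
        for j, term in enumerate(TERM_NAMES):
            rows.append({
                "scenario_id": rec.scenario_id,
                "replicate": rec.replicate,
                "term": term,
                "M": rec.M,
                "estimate": rec.estimate[j],
                "se": rec.se[j],
                "df": rec.df[j],
                "ci_lo": rec.ci_lo[j],
                "ci_hi": rec.ci_hi[j],
                "covered": bool(rec.covered[j]),
                "truth": rec.truth[j],
                "n_flagged_fits": rec.n_flagged_fits,
                "error": rec.error if rec.error is not None else "",
            })
    return pd.DataFrame(rows)
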