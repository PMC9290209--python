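"""Estimator-performance summaries over simulation replicates.

Per (scenario, model term): mean estimate, relative bias, empirical SD of
the estimates (the sampling variability the pooled SE should track), mean
pooled SE, their ratio, mean squared error, and empirical 95% CI coverage.
Replicates with flagged (non-converged) per-dataset fits are included —
their inflated SEs are part of the phenomenon — while replicates that
failed outright (no estimate at all) are excluded and counted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

METRIC_COLUMNS = [
    "scenario_id", "term", "truth", "mean_estimate", "relative_bias_pct",
    "abs_bias", "empirical_sd", "mean_se", "se_ratio", "mse", "coverage_pct",
    "n_reps_used", "n_reps_failed", "n_reps_flagged",
]


def summarize(records: pd.DataFrame, *, drop_flagged: bool = False) -> pd.DataFrame:
    """Collapse a long-format replicate frame into one row per (scenario, term).

    ``records`` is the output of :func:`misim.engine.records_to_frame` (it
    carries the per-term truth). ``drop_flagged`` excludes replicates with
    any flagged per-dataset fit, as a sensitivity analysis; the default
    keeps them.
    """
    if records.empty:
        raise ValueError("no replicate records to summarize")
    rows = []
    for (sid, term), g in records.groupby(["scenario_id", "term"], sort=False):
        failed = g["estimate"].isna()
        use = g[~failed]
        n_flagged = int((use["n_flagged_fits"] > 0).sum())
        if drop_flagged:
            use = use[use["n_flagged_fits"] == 0]
        n = len(use)
        if n < 2:
            raise ValueError(
                f"fewer than 2 usable replicates for {sid}/{term}; cannot summarize")
        est = use["estimate"].to_numpy()
        truth = float(use["truth"].iloc[0])
        mean_est = est.mean()
        emp_sd = est.std(ddof=1)
        mean_se = use["se"].to_numpy().mean()
        mse = np.mean((est - truth) ** 2)
        # sanity: MSE decomposes as bias^2 + (n-1)/n * sample variance
        decomp = (mean_est - truth) ** 2 + emp_sd ** 2 * (n - 1) / n
        if not np.allclose(mse, decomp, rtol=0, atol=1e-10 * max(1.0, mse)):
            raise AssertionError("MSE decomposition identity violated")
        bias = mean_est - truth
        rel_bias = 100.0 * bias / truth if truth != 0 else np.nan
        rows.append({
            "scenario_id": sid,
            "term": term,
            "truth": truth,
            "mean_estimate": mean_est,
            "relative_bias_pct": rel_bias,   # NaN flags a zero truth
            "abs_bias": bias,
            "empirical_sd": emp_sd,
            "mean_se": mean_se,
            "se_ratio": mean_se / emp_sd,
            "mse": mse,
            "coverage_pct": 100.0 * use["covered"].mean(),
            "n_reps_used": n,
            "n_reps_failed": int(failed.sum()),
            "n_reps_flagged": n_flagged,
        })
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def coverage_band(n_reps: int, nominal: float = 0.95) -> tuple[float, float]:
    """Normal-theory significance band (in %) for an empirical coverage rate.

    An observed coverage outside the band differs significantly (5% level)
    from the nominal rate given ``n_reps`` Monte Carlo replicates.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    z = stats.norm.ppf(0.975)
    half = 100.0 * z * np.sqrt(nominal * (1.0 - nominal) / n_reps)
    return 100.0 * nominal - half, 100.0 * nominal + half
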