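#!/usr/bin/env python
"""Benign-scenario calibration check.

Runs the well-behaved corner of the design — n = 1,000, 25% missingness,
correctly specified parametric imputation, M = 25 — for 250 replicates and
verifies that multiple imputation is calibrated there: near-zero bias,
SE ratio ~ 1, and CI coverage inside the Monte Carlo significance band for
every analysis-model term.

Writes results/benign_metrics.csv (and records under results/).
"""

import argparse
from pathlib import Path

import misim
from misim.reporting import RunManifest, emit_report


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=20220718)
    ap.add_argument("--n-pop", type=int, default=100_000)
    ap.add_argument("--reps", type=int, default=250)
    ap.add_argument("--out-dir", type=Path, default=Path("results/benign"))
    args = ap.parse_args()

    params = misim.default_params("cholesterol", n_pop=args.n_pop)
    pop = misim.build_super_population(params, 0.25, seed=args.seed)
    scenario = misim.Scenario(1000, 0.25, "norm", n_reps=args.reps)
    records = misim.run_scenario(scenario, pop, args.seed, progress=True)
    frame = misim.records_to_frame(records)
    metrics = misim.summarize(frame)

    lo, hi = misim.coverage_band(args.reps)
    inside = metrics["coverage_pct"].between(lo, hi).sum()
    chol = metrics[metrics["term"] == "cholesterol"].iloc[0]
    print(f"coverage band for {args.reps} replicates: ({lo:.2f}, {hi:.2f})%")
    print(f"terms with coverage inside the band: {inside}/11")
    print(f"cholesterol: relative bias {chol.relative_bias_pct:+.2f}%, "
          f"SE ratio {chol.se_ratio:.3f}, coverage {chol.coverage_pct:.1f}%")

    manifest = RunManifest(
        config_hash=RunManifest.hash_config(
            {"scenario": scenario.scenario_id, "n_pop": args.n_pop,
             "reps": args.reps}),
        master_seed=args.seed)
    written = emit_report(metrics, manifest, args.out_dir, records=frame)
    print("wrote", ", ".join(str(p) for p in written.values()))


if __name__ == "__main__":
    main()
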