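#!/usr/bin/env python
"""Collate performance metrics across runs and draw the summary figure.

Reads the metrics tables written by 02/03, tags each row with its scenario
factors, appends the coverage significance band, and writes a combined
results/summary_metrics.csv. With --plot, draws per-term panels of
coverage and SE ratio against missingness under scratch/ (exploratory
output, not part of the deliverable).
"""

import argparse
import re
from pathlib import Path

import pandas as pd

import misim


def parse_scenario_id(sid: str) -> dict:
    m = re.match(r"(\w+)-(\w+)-n(\d+)-p(\d+)", sid)
    return {"target": m.group(1), "method": m.group(2),
            "n_sample": int(m.group(3)), "p_missing": int(m.group(4)) / 100}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in-dirs", nargs="+", type=Path,
                    default=[Path("results/benign"), Path("results/stress")])
    ap.add_argument("--out", type=Path, default=Path("results/summary_metrics.csv"))
    ap.add_argument("--plot", action="store_true")
    args = ap.parse_args()

    tables = []
    for d in args.in_dirs:
        path = d / "metrics.csv"
        if not path.exists():
            print(f"skipping {d}: no metrics.csv (run 02/03 first)")
            continue
        tables.append(pd.read_csv(path))
    if not tables:
        raise SystemExit("no metrics found")
    metrics = pd.concat(tables, ignore_index=True)
    factors = metrics["scenario_id"].apply(parse_scenario_id).apply(pd.Series)
    metrics = pd.concat([factors, metrics], axis=1)
    bands = metrics["n_reps_used"].apply(lambda n: misim.coverage_band(int(n)))
    metrics["coverage_band_lo"] = [b[0] for b in bands]
    metrics["coverage_band_hi"] = [b[1] for b in bands]
    metrics["coverage_significant"] = ~metrics["coverage_pct"].between(
        metrics["coverage_band_lo"], metrics["coverage_band_hi"])
    args.out.parent.mkdir(parents=True, exist_ok=True)
    metrics.to_csv(args.out, index=False, float_format="%.10g")
    n_sig = int(metrics["coverage_significant"].sum())
    print(f"wrote {args.out}: {len(metrics)} (scenario, term) cells, "
          f"{n_sig} with coverage significantly off 95%")

    if args.plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        out = Path("scratch")
        out.mkdir(exist_ok=True)
        for quantity in ("coverage_pct", "se_ratio", "relative_bias_pct"):
            fig, axes = plt.subplots(3, 4, figsize=(14, 9), sharex=True)
            for ax, (term, g) in zip(axes.ravel(), metrics.groupby("term")):
                for key, gg in g.groupby(["method", "n_sample"]):
                    gg = gg.sort_values("p_missing")
                    ax.plot(gg["p_missing"], gg[quantity], marker="o",
                            label=f"{key[0]} n={key[1]}")
                ax.set_title(term, fontsize=9)
            axes[0, 0].legend(fontsize=6)
            fig.suptitle(quantity)
            fig.savefig(out / f"{quantity}.png", dpi=100)
            plt.close(fig)
        print(f"plots under {out}/")


if __name__ == "__main__":
    main()
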