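#!/usr/bin/env python
"""Run the statistical comparison battery on the two-arm study.

Consumes results/two_arm_study/metrics.csv (written by
03_synthetic_study.py), runs the within-design and across-design
Kruskal-Wallis comparisons at alpha = 0.05, the through-origin scatter
fits, the success counts, and the asymmetric-IQR outlier screen.

Writes results/stats_battery.json and prints the significant findings.
"""

from pathlib import Path

import pandas as pd

from fractalmea.quantify import METRIC_COLUMNS
from fractalmea.stats import run_comparison_battery

METRICS = Path("results/two_arm_study/metrics.csv")


def main() -> None:
    if not METRICS.exists():
        raise SystemExit(f"{METRICS} not found - run 03_synthetic_study.py first")
    metrics = pd.read_csv(METRICS)
    designs = {
        str(d): g[list(METRIC_COLUMNS)].reset_index(drop=True)
        for d, g in metrics.groupby("design")
    }
    rep = run_comparison_battery(designs)
    rep.to_json("results/stats_battery.json")
    rep.to_frame().to_csv("results/stats_battery.csv", index=False)

    print(f"cohorts: {rep.n}")
    for design, tests in rep.within.items():
        for name, t in tests.items():
            mark = t.stars or "ns"
            print(f"within {design:7} {name:14} H={t.statistic:6.2f} p={t.p:.4f} {mark}")
    for name, t in rep.across.items():
        mark = t.stars or "ns"
        print(f"across {name:6} H={t.statistic:6.2f} p={t.p:.4f} {mark}")
    print(f"success counts: {rep.success}")


if __name__ == "__main__":
    main()
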