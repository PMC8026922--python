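#!/usr/bin/env python
"""Summarise the finished grid: trend directions and the 90% LYG rule.

Reads results/grid/outcomes.csv (produced by 02_run_primary_grid.py) and
reports, per strategy, how LYG, incidence/mortality reduction, AMR and
ADR move from scenario 1 to scenario 10, and the first scenario at which
each stool strategy reaches 90% of colonoscopy's LYG — the conventional
comparable-effectiveness threshold.
"""

from pathlib import Path

import pandas as pd

GRID = Path(__file__).resolve().parents[1] / "results" / "grid"


def main():
    df = pd.read_csv(GRID / "outcomes.csv")
    print("scenario 1 -> 10 movement (per 1000 eligible at 40):")
    for strat, g in df.groupby("strategy"):
        g = g.set_index("scenario")
        lyg1, lyg10 = g.lyg[1], g.lyg[10]
        amr1, amr10 = g.weighted_amr_pct[1], g.weighted_amr_pct[10]
        direction = "down" if lyg10 < lyg1 else "up"
        print(f"  {strat:12s} LYG {lyg1:6.1f} -> {lyg10:6.1f} ({direction});"
              f" AMR {amr1:5.1f}% -> {amr10:5.1f}%")

    pct = df[df.strategy != "colonoscopy"].dropna(subset=["pct_lyg_vs_colonoscopy"])
    print("\n90% of colonoscopy LYG (comparable effectiveness):")
    for strat, g in pct.groupby("strategy"):
        g = g.sort_values("scenario")
        hit = g[g.pct_lyg_vs_colonoscopy >= 90.0]
        if len(hit):
            first = int(hit.scenario.iloc[0])
            print(f"  {strat:12s} reaches 90% at scenario {first} "
                  f"({hit.pct_lyg_vs_colonoscopy.iloc[0]:.1f}%)")
        else:
            print(f"  {strat:12s} never reaches 90% "
                  f"(max {g.pct_lyg_vs_colonoscopy.max():.1f}%)")

    adr = df[df.strategy != "colonoscopy"]
    print("\nADR at first follow-up colonoscopy, scenario 1 -> 10:")
    for strat, g in adr.groupby("strategy"):
        g = g.set_index("scenario")
        print(f"  {strat:12s} {g.adr_first_followup_pct[1]:.1f}% -> "
              f"{g.adr_first_followup_pct[10]:.1f}%"
              f" (mean exam age {g.mean_age_first_followup[1]:.1f})")


if __name__ == "__main__":
    main()
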