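#!/usr/bin/env python
"""Behavior stage: preference indices, 2x2 ANOVA, genotype PI comparison.

Reads the simulated exploration times, computes per-animal preference
indices, runs the session-level genotype x target ANOVA with Sidak
contrasts, and compares preference indices between genotypes with Welch's
t-test.
"""

from pathlib import Path

import pandas as pd

from neurometab.behavior import behavior_table, two_way_anova_sidak
from neurometab.screen import welch_t_test

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "behavior"


def main() -> None:
    animals = pd.read_csv(ROOT / "results" / "cohort" / "animals.csv")
    OUT.mkdir(parents=True, exist_ok=True)

    btab = behavior_table(animals)
    btab.to_csv(OUT / "behavior_results.csv", index=False, float_format="%.10g")

    frames = []
    for session, sub in animals.groupby("session"):
        long = pd.concat([
            sub.assign(target="target", value=sub["et_target"]),
            sub.assign(target="other", value=sub["et_other"]),
        ])
        res = two_way_anova_sidak(long)
        frames.append(res["anova"].reset_index().assign(session=session))
        inter = res["anova"].loc["interaction"]
        print(f"{session}: genotype x target interaction "
              f"F(1, {inter['df2']:.0f}) = {inter['F']:.2f}, p = {inter['p']:.2g}")
        for _, row in res["sidak"].iterrows():
            print(f"  {row['genotype']}: target vs other t({row['df']:.0f}) = "
                  f"{row['t']:.2f}, Sidak p = {row['p_sidak']:.2g}")
    pd.concat(frames).to_csv(OUT / "anova.csv", index=False, float_format="%.10g")

    pref = btab[btab["session"] == "preference"]
    wt = pref[pref["genotype"] == "WT"]["pi"]
    ko = pref[pref["genotype"] == "KO"]["pi"]
    t = welch_t_test(wt, ko)
    print(f"\npreference index, WT vs KO (Welch): t({t.df:.1f}) = {t.t:.2f}, "
          f"p = {t.p:.2g} (WT mean {t.mean_a:.2f}, KO mean {t.mean_b:.2f})")


if __name__ == "__main__":
    main()
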