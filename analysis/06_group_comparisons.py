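#!/usr/bin/env python
"""Group-test stage: per-feature genotype comparisons in both regions.

Welch's t-test (default, with the Student variant available) on every
derived feature column, highlighting the features the screen selected.
"""

from pathlib import Path

import pandas as pd

from neurometab.features import apply_crlb_filter, derive_features
from neurometab.screen import group_tests

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    meas = pd.read_csv(ROOT / "results" / "cohort" / "metabolites.csv")
    animals = pd.read_csv(ROOT / "results" / "cohort" / "animals.csv")
    genotypes = animals.drop_duplicates("id").set_index("id")["genotype"]

    filtered = apply_crlb_filter(meas)
    feats = derive_features(filtered)
    gt = pd.concat(
        [group_tests(feats, genotypes, region, "welch") for region in ("PFC", "HPC")],
        ignore_index=True,
    )
    gt.to_csv(OUT / "group_tests.csv", index=False, float_format="%.10g")

    key = gt[gt["feature"].isin(["Glu/GABA", "tCr", "NAA/tCr", "Glx", "PCr/tCr"])]
    print("key-feature genotype comparisons (Welch, two-tailed):")
    print(key[["region", "feature", "mean_a", "mean_b", "t", "df", "p"]]
          .rename(columns={"mean_a": "mean_KO", "mean_b": "mean_WT"})
          .round(4).to_string(index=False))
    sig = gt[gt["p"] < 0.05]
    print(f"\n{len(sig)} of {len(gt)} feature comparisons significant at 0.05")


if __name__ == "__main__":
    main()
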