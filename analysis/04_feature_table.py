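#!/usr/bin/env python
"""Feature stage: CRLB filter, inclusion rule, derived sums and ratios.

Applies the CRLB <= 50% measurement filter, the per-genotype n >= 5
inclusion rule, and derives tCr, Glx and the Glu/GABA, GABA/Glu, NAA/tCr,
PCr/tCr ratios per animal and region.
"""

from pathlib import Path

import pandas as pd

from neurometab.features import apply_crlb_filter, derive_features, metabolite_inclusion

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "features"


def main() -> None:
    meas = pd.read_csv(ROOT / "results" / "cohort" / "metabolites.csv")
    animals = pd.read_csv(ROOT / "results" / "cohort" / "animals.csv")
    genotypes = animals.drop_duplicates("id").set_index("id")["genotype"]
    OUT.mkdir(parents=True, exist_ok=True)

    filtered = apply_crlb_filter(meas, max_crlb_pct=50)
    print(f"CRLB filter removed {len(filtered.attrs['filter_log'])} of "
          f"{len(meas)} measurements")

    inclusion = metabolite_inclusion(filtered, genotypes, min_n=5, mode="per_group")
    inclusion.to_csv(OUT / "inclusion_report.csv")
    excl = inclusion[~inclusion["included"]]
    print(f"{int(inclusion['included'].sum())}/{len(inclusion)} (region, metabolite) "
          "columns pass the per-genotype n >= 5 rule")
    if len(excl):
        print("excluded:", ", ".join(f"{r}:{m}" for r, m in excl.index))

    feats = derive_features(filtered)
    feats.to_csv(OUT / "features.csv", float_format="%.10g")
    pfc = feats.xs("PFC", level="region")
    print("\nPFC derived features (mean over animals with complete data):")
    print(pfc[["tCr", "Glx", "Glu/GABA", "NAA/tCr", "PCr/tCr"]].mean().round(3).to_string())


if __name__ == "__main__":
    main()
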