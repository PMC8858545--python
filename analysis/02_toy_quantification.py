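#!/usr/bin/env python
"""Demonstrate the toy spectral quantifier that motivates the CRLB filter.

Synthesizes a linear-combination spectrum at increasing noise levels,
refits it, and tabulates how each metabolite's CRLB %SD grows with noise —
the mechanism by which weak resonances end up above the 50% quality
threshold in real data.
"""

from pathlib import Path

import pandas as pd

from neurometab.quant import (
    default_basis,
    default_ppm_axis,
    fit_linear_combination,
    synthesize_spectrum,
)

OUT = Path(__file__).resolve().parents[1] / "results"
TRUE = {"NAA": 8.0, "Cr": 4.0, "PCr": 4.0, "Glu": 9.0, "Gln": 3.0,
        "GABA": 2.0, "Ins": 5.0, "Tau": 8.0, "Lac": 2.0, "Ala": 0.8}


def main() -> None:
    basis = default_basis()
    ppm = default_ppm_axis(1024)
    rows = []
    for noise_sd in (0.005, 0.02, 0.08, 0.2):
        s = synthesize_spectrum(basis, TRUE, baseline_coeffs=(0.3, 0.05),
                                noise_sd=noise_sd, seed=11, ppm=ppm)
        res = fit_linear_combination(s, basis, noise_sd=noise_sd)
        for m, c in TRUE.items():
            rows.append({"noise_sd": noise_sd, "metabolite": m, "true": c,
                         "estimate": res.concentrations[m],
                         "crlb_pct": res.crlb_pct[m]})
    df = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "quant_demo.csv", index=False, float_format="%.6g")

    wide = df.pivot_table(index="metabolite", columns="noise_sd", values="crlb_pct")
    print("CRLB %SD by noise level (columns = noise SD):")
    print(wide.round(1).to_string())
    worst = wide[0.2].idxmax()
    print(f"\nat the highest noise level, {worst} is least reliable "
          f"({wide.loc[worst, 0.2]:.0f}% SD) — low-amplitude resonances cross "
          "the 50% filter threshold first, exactly as the quality filter assumes")


if __name__ == "__main__":
    main()
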