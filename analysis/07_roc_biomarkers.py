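#!/usr/bin/env python
"""Biomarker stage: logistic fits and binormal ROC curves for the hits.

Evaluates how well each screened prefrontal feature separates the two
genotypes: simple logistic regression trained on all samples, binormal
ROC with Hanley-McNeil 95% CI, and the Youden-optimal cutoff with
empirical sensitivity/specificity.  The positive class is stated
explicitly (WT here: the features are higher in wild-type animals).
"""

from pathlib import Path

import pandas as pd

from neurometab.features import apply_crlb_filter, derive_features
from neurometab.plots import roc_plot
from neurometab.roc import binormal_roc, fit_simple_logistic

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "roc"
POSITIVE = "WT"
FEATURES = ("Glu/GABA", "tCr", "NAA/tCr")


def main() -> None:
    meas = pd.read_csv(ROOT / "results" / "cohort" / "metabolites.csv")
    animals = pd.read_csv(ROOT / "results" / "cohort" / "animals.csv")
    genotypes = animals.drop_duplicates("id").set_index("id")["genotype"]
    OUT.mkdir(parents=True, exist_ok=True)

    feats = derive_features(apply_crlb_filter(meas)).xs("PFC", level="region")
    rows, curves = [], []
    for feat in FEATURES:
        col = feats[feat].dropna()
        g = genotypes.loc[col.index]
        pos = col[g == POSITIVE].to_numpy()
        neg = col[g != POSITIVE].to_numpy()
        logit = fit_simple_logistic(col.to_numpy(), (g == POSITIVE).astype(int).to_numpy())
        rr = binormal_roc(neg, pos, feature=feat, positive=POSITIVE, auto_flip=True)
        curves.append(rr)
        rows.append({
            "feature": feat, "positive": POSITIVE, "auc": rr.auc,
            "auc_ci_low": rr.auc_ci_low, "auc_ci_high": rr.auc_ci_high,
            "cutoff": rr.cutoff, "sensitivity_pct": rr.sensitivity_pct,
            "specificity_pct": rr.specificity_pct, "flipped": rr.flipped,
            "logistic_slope": logit.slope, "separated": logit.separated,
            "n_pos": rr.n1, "n_neg": rr.n0,
        })
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "roc_results.csv", index=False, float_format="%.6g")
    roc_plot(curves, OUT / "roc_curves.svg")

    print(f"binormal ROC, positive class = {POSITIVE} "
          "(in-sample training, no cross-validation):")
    print(table[["feature", "auc", "auc_ci_low", "auc_ci_high", "cutoff",
                 "sensitivity_pct", "specificity_pct"]].round(3).to_string(index=False))


if __name__ == "__main__":
    main()
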