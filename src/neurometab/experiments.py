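"""Calibration and recovery experiments at the study's scale.

Each function runs a self-contained simulation experiment against the
package's own machinery and returns the measured quantities:

* type-I-error calibration of the permutation p-value,
* agreement between the sampled permutation null and exhaustive enumeration,
* the binormal AUC closed form versus large-sample empirical AUC,
* recovery of a planted Glu/GABA signal at the cohort size of the study
  (9 wild-type vs 11 knockout animals),
* null-cohort false-positive rates for the screen and the Welch test,
* recovery and noise-scaling behavior of the toy spectral quantifier.

All functions are deterministic given their seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .features import apply_crlb_filter, derive_features, metabolite_inclusion
from .quant import default_basis, default_ppm_axis, fit_linear_combination, synthesize_spectrum
from .roc import binormal_roc, empirical_auc
from .screen import group_tests, permutation_pvalue, screen
from .synth import CohortSpec, generate_cohort, generative_feature_samples

__all__ = [
    "permutation_calibration",
    "exhaustive_vs_sampled",
    "binormal_closed_form_check",
    "glu_gaba_recovery",
    "null_screen_calibration",
    "quantifier_recovery",
]


def permutation_calibration(
    n: int = 20, B: int = 2000, n_rep: int = 1000, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Empirical rejection rate of the permutation test under independence.

    Draws ``n_rep`` pairs of independent Gaussian vectors of length ``n``
    and reports how often the two-sided permutation p falls below alpha.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_rep):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        p = permutation_pvalue(x, y, B=B, seed=rng)
        rejections += p < alpha
    return {"rejection_rate": rejections / n_rep, "n_rep": n_rep, "n": n, "B": B}


def exhaustive_vs_sampled(n: int = 7, B: int = 5000, seed: int = 0) -> dict:
    """Exact (n!-enumeration) vs sampled permutation p on one dataset.

    Also reports the Monte-Carlo standard error of the sampled estimate so
    callers can check |p_sampled - p_exact| against it.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = 0.6 * x + rng.normal(size=n)  # moderate signal: p away from both 0 and 1
    p_exact = permutation_pvalue(x, y, method="exhaustive")
    p_sampled = permutation_pvalue(x, y, B=B, seed=rng)
    se = float(np.sqrt(p_exact * (1 - p_exact) / B))
    return {"p_exact": p_exact, "p_sampled": p_sampled, "mc_se": se, "n": n, "B": B}


def binormal_closed_form_check(n_per_class: int = 100_000, seed: int = 0) -> dict:
    """Binormal AUC closed form vs large-sample empirical (trapezoidal) AUC.

    Classes are separated by exactly sqrt(sigma0^2 + sigma1^2), so the
    closed-form AUC is Phi(1).
    """
    mu0, s0, s1 = 0.0, 1.0, 1.5
    delta = float(np.sqrt(s0**2 + s1**2))
    rng = np.random.default_rng(seed)
    neg = rng.normal(mu0, s0, n_per_class)
    pos = rng.normal(mu0 + delta, s1, n_per_class)
    auc_closed = float(stats.norm.cdf(1.0))
    auc_emp = empirical_auc(neg, pos)
    fitted = binormal_roc(neg, pos)
    return {
        "auc_closed_form": auc_closed,
        "auc_empirical": auc_emp,
        "auc_binormal_fit": fitted.auc,
        "n_per_class": n_per_class,
    }


def generative_auc(spec: CohortSpec, region: str, feature: str, positive: str = "WT",
                   n_draws: int = 200_000, seed: int = 99) -> float:
    """Ground-truth AUC of a feature implied by a cohort spec (Monte Carlo).

    Derived ratio features are ratios of correlated normals, so the truth
    AUC is evaluated by large-n sampling from the generative model rather
    than a Gaussian formula.
    """
    rng = np.random.default_rng(seed)
    neg_label = "KO" if positive == "WT" else "WT"
    pos = generative_feature_samples(spec, region, feature, positive, n_draws, rng)
    neg = generative_feature_samples(spec, region, feature, neg_label, n_draws, rng)
    return empirical_auc(neg, pos)


def _cohort_feature_tables(spec: CohortSpec):
    from .behavior import behavior_table

    animals, measurements, _ = generate_cohort(spec)
    filtered = apply_crlb_filter(measurements)
    genotypes = animals.drop_duplicates("id").set_index("id")["genotype"]
    inclusion = metabolite_inclusion(filtered, genotypes)
    feats = derive_features(filtered)
    btab = behavior_table(animals)
    pi = btab[btab["session"] == "preference"].set_index("id")["pi"]
    return animals, genotypes, inclusion, feats, pi


def glu_gaba_recovery(n_rep: int = 200, B: int = 2000, seed: int = 0) -> dict:
    """Recovery of the planted prefrontal Glu/GABA signal at n = 9 + 11.

    Over replicate cohorts drawn from the default spec, reports (a) how
    often Glu/GABA is selected at the q95 tier of the social-preference
    screen, and (b) the mean binormal AUC estimate against the generative
    ground-truth AUC.
    """
    base = CohortSpec()
    truth_auc = generative_auc(base, "PFC", "Glu/GABA", positive="WT",
                               seed=int(seed) + 1_000_003)
    selected = 0
    aucs = []
    root = np.random.SeedSequence(seed)
    child_seeds = root.generate_state(n_rep)
    for rep in range(n_rep):
        spec = CohortSpec(seed=int(child_seeds[rep] % (2**31)))
        animals, genotypes, inclusion, feats, pi = _cohort_feature_tables(spec)
        results = screen(feats, pi, "PFC", "preference", B=B,
                         seed=spec.seed, included=inclusion)
        hit = next((r for r in results if r.feature == "Glu/GABA"), None)
        if hit is not None and hit.tier in ("q95", "q975"):
            selected += 1
        col = feats.xs("PFC", level="region")["Glu/GABA"].dropna()
        g = genotypes.loc[col.index]
        rr = binormal_roc(col[g == "KO"].to_numpy(), col[g == "WT"].to_numpy(),
                          positive="WT")
        aucs.append(rr.auc)
    return {
        "q95_selection_rate": selected / n_rep,
        "mean_estimated_auc": float(np.mean(aucs)),
        "generative_auc": truth_auc,
        "n_rep": n_rep,
        "B": B,
    }


def null_screen_calibration(n_rep: int = 500, B: int = 2000, seed: int = 0) -> dict:
    """False-positive rates on zero-effect cohorts.

    Cohorts are generated with no genotype effects and no latent coupling,
    so every feature-behavior association and every group difference is
    null.  Reports the across-feature mean q95 flag rate of the screen and
    the mean rejection rate of the Welch t-test at 0.05.
    """
    root = np.random.SeedSequence(seed)
    child_seeds = root.generate_state(n_rep)
    q95_flags = q95_total = 0
    welch_rej = welch_total = 0
    for rep in range(n_rep):
        spec = CohortSpec(
            seed=int(child_seeds[rep] % (2**31)),
            latent_coupling={},
            genotype_effects={},
        )
        animals, genotypes, inclusion, feats, pi = _cohort_feature_tables(spec)
        results = screen(feats, pi, "PFC", "preference", B=B,
                         seed=spec.seed, included=inclusion)
        q95_flags += sum(r.tier in ("q95", "q975") for r in results)
        q95_total += len(results)
        gt = group_tests(feats, genotypes, "PFC", "welch")
        welch_rej += int((gt["p"] < 0.05).sum())
        welch_total += len(gt)
    return {
        "q95_flag_rate": q95_flags / q95_total,
        "welch_rejection_rate": welch_rej / welch_total,
        "n_rep": n_rep,
        "B": B,
    }


def quantifier_recovery(n_seeds: int = 100, seed: int = 0) -> dict:
    """Toy-quantifier accuracy and CRLB noise scaling.

    (a) A noiseless spectrum is refit and the maximum relative
    concentration error reported.  (b) Over ``n_seeds`` noise realizations
    the same spectrum is fit at noise_sd and 2x noise_sd (same noise shape,
    scaled), and the mean ratio of CRLB %SD values is reported; the CRLB
    is proportional to the noise SD, so the expected ratio is 2.
    """
    basis = default_basis()
    ppm = default_ppm_axis(1024)
    true = {"NAA": 8.0, "Cr": 4.0, "PCr": 4.0, "Glu": 9.0, "Gln": 3.0,
            "GABA": 2.0, "Ins": 5.0, "Tau": 8.0, "Lac": 2.0, "Ala": 0.8}
    clean = synthesize_spectrum(basis, true, baseline_coeffs=(0.5, 0.1), ppm=ppm)
    res0 = fit_linear_combination(clean, basis, noise_sd=1.0)
    max_rel_err = max(
        abs(res0.concentrations[m] - c) / c for m, c in true.items()
    )

    sigma = 0.02
    rng = np.random.default_rng(seed)
    ratios = []
    for _ in range(n_seeds):
        noise = rng.normal(0.0, 1.0, size=ppm.shape)
        s1 = synthesize_spectrum(basis, true, baseline_coeffs=(0.5, 0.1), ppm=ppm)
        lo = type(s1)(ppm=ppm, intensity=s1.intensity + sigma * noise)
        hi = type(s1)(ppm=ppm, intensity=s1.intensity + 2 * sigma * noise)
        r1 = fit_linear_combination(lo, basis, noise_sd=sigma)
        r2 = fit_linear_combination(hi, basis, noise_sd=2 * sigma)
        for m in true:
            if np.isfinite(r1.crlb_pct[m]) and np.isfinite(r2.crlb_pct[m]):
                ratios.append(r2.crlb_pct[m] / r1.crlb_pct[m])
    return {
        "max_rel_error_noiseless": float(max_rel_err),
        "mean_crlb_ratio": float(np.mean(ratios)),
        "n_seeds": n_seeds,
    }
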