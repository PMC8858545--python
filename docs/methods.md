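# Methods

## The analysis model

The pipeline treats a behavioral-MRS study as three coupled estimation
problems on a cohort of `n_wt + n_ko` animals.

**Behavior.** Exploration times in the three-chamber assay are summarized
per animal and session by the preference index
`PI = (ET_target − ET_other)/(ET_target + ET_other)`. Session-level group
structure is tested with a 2×2 two-way ANOVA (genotype × target) computed
from single-degree-of-freedom contrasts of the four cell means with the
pooled error mean square (Type III / unweighted-means form, valid for
unbalanced cells), followed by within-genotype target contrasts with Sidak
adjustment `p_adj = 1 − (1 − p)^2`. The two targets of one animal are
treated as independent observations (ordinary between-cell ANOVA, not
repeated measures); this matches the conventional presentation of this
assay. An animal with zero total exploration has an undefined PI and is
excluded with an explicit log entry rather than coerced to 0.

**Feature construction.** Quantified measurements carry a Cramér–Rao lower
bound expressed as %SD. A measurement is retained iff CRLB ≤ 50%
(inclusive boundary), and a (region, metabolite) column enters the
analysis only if at least `min_n = 5` animals per genotype survive. The
count rule is genuinely ambiguous in the field's usual phrasing ("greater
than 5" alongside displayed groups of exactly 5); the default
`per_group, ≥ 5` reproduces the displayed behavior, and a strict
`total, > 5` mode is provided. Filtered values become missing — never zero
and never imputed — and all downstream statistics use pairwise-complete
observations, so per-feature n varies. Derived features are tCr = Cr + PCr,
Glx = Gln + Glu, and the ratios Glu/GABA, GABA/Glu, NAA/tCr, PCr/tCr; a
derived cell is missing whenever any component is, and a non-positive
denominator yields a missing cell with a log entry, never an infinity.
Concentration units are treated as opaque throughout.

**Correlation screen.** For each feature, Pearson's r against the behavior
index is calibrated by an empirical permutation null: B = 5000 random
re-pairings of the behavior values against the fixed feature values, with
the add-one estimator `p = (1 + #{|r_b| ≥ |r_obs|})/(B + 1)` so p is a
valid p-value at finite B and never 0. The test is two-sided on |r| by
default (both signs of correlation are of interest); one-sided modes
exist. At n ≤ 7 an exhaustive mode enumerates all n! pairings and is exact.
No across-feature multiplicity correction is applied by default — the
permutation p is reported per feature with q95/q975 tier flags — and an
optional Benjamini–Hochberg step is clearly labeled as an extension. Each
(feature, region, index) triple gets its own RNG stream derived from the
master seed (CRC32 of the triple name mixed into a `SeedSequence`), so
results do not depend on screening order or on which other features are
present.

**Group tests.** Welch's unequal-variance t-test (Satterthwaite df,
two-tailed) is the default genotype comparison; the pooled-variance
Student variant is available because both conventions appear in this
literature. Two constant equal groups return p = 1 by convention with a
note.

**Biomarker evaluation.** A single-feature logistic regression is fit by
IRLS (tolerance 1e-8, ≤ 100 iterations) on all samples — deliberately
in-sample, as small cohorts in this field are typically evaluated, and
flagged as such in every output. Complete separation is detected when the
standardized slope exceeds a cap (30 per feature-SD) and reported with
capped coefficients rather than a divergent fit. Discrimination is
summarized by the binormal ROC: class-conditional normals fitted by sample
moments, `AUC = Φ((μ₁ − μ₀)/√(σ₀² + σ₁²))`, 95% CI from the Hanley–McNeil
standard error (a seeded bootstrap alternative is provided), and the
operating cutoff maximizing Youden's J, which for the binormal curve is
the class-density crossing point (midpoint for equal variances, a
quadratic root otherwise; an equal-spacing grid search is used as the test
oracle). The positive class is a required explicit argument — with 9 vs 11
animals the sensitivity/specificity fractions depend on it, and no silent
default is defensible. Orientation follows higher score = more positive;
`auto_flip` optionally negates the score axis when AUC < 0.5 and records
the flip.

## The synthetic cohort generator

One latent sociability score per animal, `s ~ Normal(μ_genotype, 1)` with
defaults μ_WT = 1, μ_KO = 0, drives both observables:

* the preference index is `0.45·s + Normal(0, 0.15)`, clipped to [−1, 1]
  and converted exactly to exploration times over a 600 s session, so
  wild-types average PI ≈ 0.45 and knockouts sit at no-preference;
* each metabolite concentration is
  `baseline + effect·1[KO] + coupling·s + Normal(0, sd)`, truncated at 0.

Defaults plant the signal pattern this kind of study reports: knockouts
have lower prefrontal Glu and higher GABA (so the Glu/GABA ratio drops),
lower prefrontal Cr and PCr (so tCr drops and NAA/tCr rises), and higher
hippocampal Glu and Gln (so Glx rises); the latent coupling acts on the
prefrontal components only, making prefrontal features — and only they —
correlate with the preference index. Ratios are never drawn directly: the
generator shifts components and the pipeline must derive the ratios, which
keeps the derivation code honestly exercised. The KO genotype shift on the
Glu/GABA components is sized so the ground-truth AUC of the derived ratio
is ≈ 0.84, a typical single-feature biomarker strength for such cohorts;
the behavior coupling (0.45 latent slope, 0.15 PI noise) puts the
population correlation between PI and Glu/GABA near 0.63, which at
n = 9 + 11 gives ~85% power at the q95 tier — a clearly-detectable but not
saturated signal. Because a ratio of correlated normals has no Gaussian
closed form, ground-truth feature distributions (and hence generative AUC)
are evaluated by large-n Monte Carlo from the truth record.

CRLB %SD values are drawn per metabolite from a shifted gamma,
`loc + Gamma(shape, scale)`, in three tiers: well-quantified singlet-like
metabolites (median ≈ 7%), weak/overlapped ones (Ala, NAAG, GPC, PCh, Cr;
a tail crossing 50%), and near-threshold ones (Glc, Lac, Scyllo; usually
above 50%). Under the default spec this leaves ~28 of 34 (region,
metabolite) columns included with per-feature n varying — the missingness
pattern the filter logic must handle. CRLBs are drawn independently of the
concentration noise; the toy quantifier demonstrates the mechanistic
coupling separately.

**What the generator does not emulate:** scanner physics and acquisition
artifacts, region- or metabolite-correlated noise beyond the single latent
factor, non-Gaussian behavioral distributions, repeated sessions, litter
or batch effects. Passing tests therefore show that the statistical
machinery is correct and calibrated under the assumed generative
structure, not that the biological effect sizes are right.

## The toy quantifier

Spectra are linear combinations of per-metabolite basis lineshapes (sums
of Lorentzian or Gaussian peaks on a decreasing ppm grid) plus a
polynomial baseline (degree 2 default, scaled to [−1, 1] for conditioning)
and white noise. Fitting is bounded linear least squares (concentrations
≥ 0, baseline free); the covariance of the estimates is
`σ²(G_AᵀG_A)⁻¹` on the active set, and CRLB %SD = 100·√var/estimate, with
∞ reported for a zero estimate. Noise σ is taken from the synthesis truth
when known, otherwise estimated from the fit residual in a signal-free
window (default 9–10 ppm). Collinear basis vectors are detected (pairwise
column correlation > 1 − 1e−10, or rank deficiency) and reported by
metabolite name. Because the model is linear, the noiseless fit recovers
inputs to machine precision and CRLB scales exactly linearly in σ — both
are regression-tested. This module is a synthetic stand-in whose purpose
is mechanistic CRLB generation; its outputs are never compared to any
clinical quantifier's.

## Numerical choices

* Permutation comparisons use a 1e−14 tolerance on |r| so floating-point
  ties count as exceedances (conservative).
* The permutation null is computed vectorized (one (B, n) permuted matrix
  per feature, centered matmul), which keeps 500-cohort calibration runs
  in minutes on one CPU.
* Sample moments use ddof = 1 everywhere a class or group SD is reported.
* Hanley–McNeil CIs are clipped to [0, 1] and widened to contain the point
  estimate.
* ANOVA contrast F-statistics are algebraically exact for the 2×2 layout;
  the statsmodels Type III OLS is the independent oracle in tests.

## Experiment scales

The calibration experiments (`neurometab.experiments`, also behind
`scripts/acceptance.py`) use 1000 replicates for permutation type-I-error
calibration (n = 20, B = 2000), 200 replicate cohorts for signal recovery,
500 for null sanity, and 100 fits for CRLB noise scaling — sizes chosen so
Monte-Carlo error is small against the tested bounds while the whole suite
runs in a few minutes on one CPU.

## Known limitations

* The binormal ROC assumes within-class normality; for the derived ratio
  features this is an approximation (the generator's ratio features are
  ratios of normals), which is why recovery is checked against
  Monte-Carlo generative truth rather than a normal formula.
* In-sample logistic/ROC training overstates out-of-sample performance by
  construction; the pipeline reports it with a warning note and provides
  no cross-validation.
* The per-group ≥ 5 inclusion default is one resolution of an ambiguous
  field convention; analyses sensitive to it should run both modes.
* The two-way ANOVA treats the two targets of one animal as independent
  observations; a repeated-measures model would be more conservative.
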