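"""Single-feature biomarker evaluation: logistic regression + binormal ROC.

The binormal model assumes the discriminant score is Gaussian within each
class, X0 ~ N(mu0, sigma0^2) for negatives and X1 ~ N(mu1, sigma1^2) for
positives (higher score = more positive).  The ROC curve is then

    TPR(c) = Phi((mu1 - c) / sigma1),   FPR(c) = Phi((mu0 - c) / sigma0)

over cutoffs c, with area under the curve

    AUC = Phi((mu1 - mu0) / sqrt(sigma0^2 + sigma1^2)).

The 95% confidence interval uses the Hanley–McNeil standard error; a
seeded bootstrap alternative is provided.  The operating cutoff maximizes
Youden's J = sensitivity + specificity - 1, which for the binormal curve
has a closed form (density-crossing point); the reported sensitivity and
specificity are also evaluated empirically at that cutoff.

A simple (single-feature) logistic regression is fit by iteratively
reweighted least squares on all samples, matching an in-sample training
protocol; complete separation is detected and reported via a flag with
capped coefficients rather than a diverging fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ROCResult",
    "LogisticFit",
    "fit_simple_logistic",
    "binormal_roc",
    "optimal_cutoff",
    "empirical_auc",
]

_Z95 = float(stats.norm.ppf(0.975))


@dataclass
class LogisticFit:
    """Maximum-likelihood simple logistic regression P(y=1|x) = expit(b0 + b1 x)."""

    intercept: float
    slope: float
    converged: bool
    n_iter: int
    separated: bool = False

    def predict(self, x) -> np.ndarray:
        from scipy.special import expit

        return expit(self.intercept + self.slope * np.asarray(x, dtype=float))


def fit_simple_logistic(
    x, y, tol: float = 1e-8, max_iter: int = 100, cap: float = 30.0
) -> LogisticFit:
    """Fit a single-feature logistic regression by IRLS.

    Parameters
    ----------
    x : array-like
        Feature values.
    y : array-like
        Binary labels (0/1 or two distinct labels; the larger sorts as 1).
    tol : float
        Convergence tolerance on the max absolute coefficient update.
    max_iter : int
        IRLS iteration cap.
    cap : float
        Bound on |slope| * sd(x): beyond it the classes are treated as
        (quasi-)separated, the coefficients are capped at that scale and
        ``separated`` is flagged instead of letting the slope diverge.

    Raises
    ------
    ValueError
        If only one class is present or n < 4.
    """
    x = np.asarray(x, dtype=float)
    labels = np.unique(np.asarray(y))
    if len(labels) != 2:
        raise ValueError(f"need exactly two classes, got {labels}")
    yb = (np.asarray(y) == labels[1]).astype(float)
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    sx = x.std(ddof=0)
    if sx == 0:
        # feature carries no information: slope 0, intercept = logit(prevalence)
        p = yb.mean()
        return LogisticFit(float(np.log(p / (1 - p))), 0.0, True, 0)

    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    converged = False
    separated = False
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -700, 700)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        # Newton step via weighted least squares
        XtW = X.T * w
        try:
            step = np.linalg.solve(XtW @ X, X.T @ (yb - mu))
        except np.linalg.LinAlgError:
            separated = True
            break
        beta = beta + step
        if abs(beta[1]) * sx > cap:
            separated = True
            beta[1] = np.sign(beta[1]) * cap / sx
            beta[0] = -beta[1] * x.mean() + np.log(yb.mean() / (1 - yb.mean() + 1e-12))
            break
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    return LogisticFit(float(beta[0]), float(beta[1]), converged, it, separated)


@dataclass
class ROCResult:
    """Binormal ROC evaluation of one feature for one positive class."""

    feature: str
    positive: str
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    cutoff: float
    sensitivity_pct: float
    specificity_pct: float
    mu0: float
    sigma0: float
    mu1: float
    sigma1: float
    n0: int
    n1: int
    curve: np.ndarray = field(repr=False)  # (K, 2) array of (FPR, TPR)
    flipped: bool = False
    degenerate: bool = False
    logistic: LogisticFit | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC outside [0, 1]")


def hanley_mcneil_se(auc: float, n0: int, n1: int) -> float:
    """Hanley–McNeil (1982) standard error of an AUC estimate."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n0 * n1)
    return float(np.sqrt(max(var, 0.0)))


def empirical_auc(neg, pos) -> float:
    """Empirical AUC = P(pos > neg) + 0.5 P(tie) (Mann–Whitney form)."""
    neg = np.asarray(neg, dtype=float)
    pos = np.asarray(pos, dtype=float)
    ranks = stats.rankdata(np.concatenate([neg, pos]))
    u = ranks[len(neg):].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(neg) * len(pos)))


def binormal_roc(
    neg,
    pos,
    feature: str = "",
    positive: str = "positive",
    n_curve: int = 512,
    auto_flip: bool = False,
    ci_method: str = "hanley-mcneil",
    n_boot: int = 2000,
    seed: int | None = None,
) -> ROCResult:
    """Binormal ROC from per-class feature values.

    Parameters
    ----------
    neg, pos : array-like
        Feature values in the negative and positive class.
    positive : str
        Label of the positive class (reported, no silent default in
        pipeline outputs: callers must name it).
    auto_flip : bool
        If True and the fitted AUC < 0.5, negate the score axis so that
        higher = more positive; the flip is recorded in ``flipped``.
    ci_method : {"hanley-mcneil", "bootstrap"}
        95% CI method; bootstrap resamples both classes ``n_boot`` times
        with the given seed.

    The convention is higher score = more positive; the curve is traced
    over cutoffs spanning both class distributions.
    """
    neg = np.asarray(neg, dtype=float)
    pos = np.asarray(pos, dtype=float)
    neg, pos = neg[np.isfinite(neg)], pos[np.isfinite(pos)]
    if len(neg) < 2 or len(pos) < 2:
        raise ValueError("each class needs at least 2 observations")
    mu0, s0 = float(neg.mean()), float(neg.std(ddof=1))
    mu1, s1 = float(pos.mean()), float(pos.std(ddof=1))
    if s0 == 0 and s1 == 0:
        if mu0 == mu1:
            raise ValueError("AUC undefined: zero variance in both classes, equal means")
        s0 = s1 = 1e-12
    pooled = float(np.sqrt(s0**2 + s1**2))

    flipped = False
    if auto_flip and mu1 < mu0:
        return_result = binormal_roc(
            -neg, -pos, feature=feature, positive=positive, n_curve=n_curve,
            auto_flip=False, ci_method=ci_method, n_boot=n_boot, seed=seed,
        )
        return_result.flipped = True
        return_result.cutoff = -return_result.cutoff
        return_result.mu0, return_result.mu1 = mu0, mu1
        return_result.sigma0, return_result.sigma1 = s0, s1
        return return_result

    auc = float(stats.norm.cdf((mu1 - mu0) / pooled))
    degenerate = abs(mu1 - mu0) < 1e-12

    lo = min(mu0 - 4 * max(s0, 1e-12), mu1 - 4 * max(s1, 1e-12))
    hi = max(mu0 + 4 * max(s0, 1e-12), mu1 + 4 * max(s1, 1e-12))
    cuts = np.linspace(hi, lo, n_curve)
    tpr = stats.norm.cdf((mu1 - cuts) / max(s1, 1e-12))
    fpr = stats.norm.cdf((mu0 - cuts) / max(s0, 1e-12))
    curve = np.column_stack([fpr, tpr])

    if ci_method == "hanley-mcneil":
        se = hanley_mcneil_se(auc, len(neg), len(pos))
        lo_ci, hi_ci = auc - _Z95 * se, auc + _Z95 * se
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            rn = rng.choice(neg, size=len(neg), replace=True)
            rp = rng.choice(pos, size=len(pos), replace=True)
            d0, d1 = rn.std(ddof=1), rp.std(ddof=1)
            denom = np.sqrt(d0**2 + d1**2)
            boots[b] = stats.norm.cdf((rp.mean() - rn.mean()) / denom) if denom > 0 else 0.5
        lo_ci, hi_ci = np.percentile(boots, [2.5, 97.5])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    lo_ci, hi_ci = float(np.clip(lo_ci, 0, 1)), float(np.clip(hi_ci, 0, 1))
    lo_ci, hi_ci = min(lo_ci, auc), max(hi_ci, auc)

    result = ROCResult(
        feature=feature, positive=positive, auc=auc,
        auc_ci_low=lo_ci, auc_ci_high=hi_ci,
        cutoff=np.nan, sensitivity_pct=np.nan, specificity_pct=np.nan,
        mu0=mu0, sigma0=s0, mu1=mu1, sigma1=s1,
        n0=len(neg), n1=len(pos), curve=curve,
        flipped=flipped, degenerate=degenerate,
    )
    cutoff, sens, spec = optimal_cutoff(result)
    result.cutoff = cutoff
    # empirical operating point at the analytic cutoff
    result.sensitivity_pct = float(100.0 * np.mean(pos >= cutoff))
    result.specificity_pct = float(100.0 * np.mean(neg < cutoff))
    result.binormal_sensitivity_pct = sens  # type: ignore[attr-defined]
    result.binormal_specificity_pct = spec  # type: ignore[attr-defined]
    return result


def optimal_cutoff(roc: ROCResult) -> tuple[float, float, float]:
    """Cutoff maximizing Youden's J on the binormal curve.

    Returns (cutoff, sensitivity %, specificity %) evaluated on the
    binormal model.  For equal variances the maximizer is the midpoint of
    the class means; otherwise it is the root of the class-density
    equality, a quadratic in the cutoff.  Degenerate (AUC = 0.5) inputs
    return the midpoint with J = 0 and the ``degenerate`` flag already set
    on the ROCResult.
    """
    mu0, s0, mu1, s1 = roc.mu0, max(roc.sigma0, 1e-12), roc.mu1, max(roc.sigma1, 1e-12)
    if roc.degenerate or abs(mu1 - mu0) < 1e-12:
        c = 0.5 * (mu0 + mu1)
    elif abs(s0 - s1) < 1e-12 * max(s0, s1):
        c = 0.5 * (mu0 + mu1)
    else:
        # phi((c-mu1)/s1)/s1 = phi((c-mu0)/s0)/s0  =>  quadratic a c^2 + b c + g = 0
        a = 1.0 / s1**2 - 1.0 / s0**2
        b = 2.0 * (mu0 / s0**2 - mu1 / s1**2)
        g = mu1**2 / s1**2 - mu0**2 / s0**2 - 2.0 * np.log(s0 / s1)
        disc = b**2 - 4 * a * g
        if disc < 0:
            c = 0.5 * (mu0 + mu1)
        else:
            roots = np.array([(-b + np.sqrt(disc)) / (2 * a), (-b - np.sqrt(disc)) / (2 * a)])
            J = stats.norm.cdf((mu1 - roots) / s1) - stats.norm.cdf((mu0 - roots) / s0)
            if mu1 < mu0:  # reversed orientation: J is negative, pick the extremum
                c = float(roots[np.argmin(J)])
            else:
                c = float(roots[np.argmax(J)])
    sens = float(100.0 * stats.norm.cdf((mu1 - c) / s1))
    spec = float(100.0 * (1.0 - stats.norm.cdf((mu0 - c) / s0)))
    return float(c), sens, spec
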