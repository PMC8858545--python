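"""Permutation-calibrated Pearson correlation screen and group tests.

For each candidate feature, the screen computes the Pearson correlation r
between the feature and a behavior index across animals, then calibrates
its significance against an *empirical null*: the distribution of r under
random re-pairing of the samples.  With B sampled permutations the
two-sided p-value uses the add-one convention

    p = (1 + #{b : |r_b| >= |r_obs|}) / (B + 1)

so p is never zero and is a valid p-value at finite B.  At small n an
exhaustive mode enumerates all n! pairings and returns the exact
permutation p.  Features are flagged at two tiers of the null
distribution: q95 (p < 0.05) and q975 (p < 0.025).

Genotype group differences are tested per feature with Welch's unequal-
variance t-test (default) or Student's pooled-variance t-test.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScreenResult",
    "GroupTestResult",
    "pearson_r",
    "permutation_pvalue",
    "screen",
    "welch_t_test",
    "student_t_test",
]


class InsufficientDataError(ValueError):
    pass


class ConstantInputError(ValueError):
    pass


def _clean_pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def pearson_r(x, y) -> float:
    """Product-moment correlation on pairwise-complete observations.

    Raises :class:`InsufficientDataError` for n < 3 and
    :class:`ConstantInputError` when either vector is constant.
    """
    x, y = _clean_pair(x, y)
    if len(x) < 3:
        raise InsufficientDataError(f"need at least 3 complete pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def _perm_r(x: np.ndarray, y_perm: np.ndarray) -> np.ndarray:
    """Pearson r of fixed x against each row of a (B, n) matrix of permuted y."""
    xc = x - x.mean()
    xc /= np.linalg.norm(xc)
    yc = y_perm - y_perm.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(yc, axis=1)
    return (yc @ xc) / norms


def permutation_pvalue(
    x,
    y,
    B: int = 5000,
    seed: int | np.random.Generator | None = None,
    sidedness: str = "two_sided",
    method: str = "sampled",
) -> float:
    """Permutation p-value for the Pearson correlation of x and y.

    Permutations shuffle y against fixed x.  ``method="sampled"`` draws B
    random permutations and applies the add-one rule; ``method="exhaustive"``
    enumerates all n! pairings (identity included, so p is never zero) and
    ignores B.  ``sidedness`` is ``two_sided`` (on |r|), ``greater`` or
    ``less``.
    """
    if sidedness not in ("two_sided", "greater", "less"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    x, y = _clean_pair(x, y)
    r_obs = pearson_r(x, y)

    def exceeds(r_null: np.ndarray) -> np.ndarray:
        if sidedness == "two_sided":
            return np.abs(r_null) >= abs(r_obs) - 1e-14
        if sidedness == "greater":
            return r_null >= r_obs - 1e-14
        return r_null <= r_obs + 1e-14

    n = len(x)
    if method == "exhaustive":
        perms = np.array(list(iter_permutations(range(n))), dtype=np.intp)
        r_null = _perm_r(x, y[perms])
        return float(np.mean(exceeds(r_null)))
    if method != "sampled":
        raise ValueError(f"unknown method {method!r}")
    if B < 1:
        raise ValueError("B must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y_perm = rng.permuted(np.broadcast_to(y, (B, n)), axis=1)
    r_null = _perm_r(x, y_perm)
    return float((1 + int(exceeds(r_null).sum())) / (B + 1))


@dataclass
class ScreenResult:
    """One feature's screen outcome against one behavior index."""

    feature: str
    region: str
    index: str
    n_pairs: int
    r: float
    r2: float
    p_perm: float
    tier: str  # none | q95 | q975
    slope: float
    intercept: float
    slope_se: float

    @property
    def neglog10_p(self) -> float:
        return -math.log10(self.p_perm)


def _feature_seed(master_seed: int, feature: str, region: str, index: str) -> np.random.Generator:
    # one stream per (feature, region, index): results are order-independent
    tag = zlib.crc32(f"{region}|{feature}|{index}".encode())
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), tag]))


def screen(
    features: pd.DataFrame,
    behavior: pd.Series,
    region: str,
    index_name: str,
    B: int = 5000,
    seed: int = 0,
    sidedness: str = "two_sided",
    included: pd.DataFrame | None = None,
) -> list[ScreenResult]:
    """Correlation screen of every feature column against a behavior index.

    Parameters
    ----------
    features : DataFrame
        Wide table indexed by (id, region) from :func:`~neurometab.features.derive_features`.
    behavior : Series
        Behavior index (e.g. social-preference PI) indexed by animal id.
    region : str
        Which region's feature rows to screen.
    index_name : str
        Name of the behavior index (labels results, seeds the per-feature
        RNG streams).
    B, seed, sidedness
        Permutation-null settings; one RNG stream per (feature, region,
        index) is derived from ``seed``.
    included : DataFrame, optional
        Inclusion flags from :func:`~neurometab.features.metabolite_inclusion`;
        raw-metabolite columns not included are skipped.  Derived features
        are screened whenever they have data.

    Tier q95 means p_perm < 0.05, q975 means p_perm < 0.025.
    """
    sub = features.xs(region, level="region")
    common = sub.index.intersection(behavior.index)
    if len(common) == 0:
        raise ValueError("no overlapping animals between feature and behavior tables")
    sub = sub.loc[common]
    b = behavior.loc[common].astype(float)

    skipped: list[dict] = []
    results: list[ScreenResult] = []
    for feat in sub.columns:
        if included is not None and (region, feat) in included.index:
            if not bool(included.loc[(region, feat), "included"]):
                skipped.append({"feature": feat, "reason": "inclusion rule"})
                continue
        x = sub[feat].astype(float)
        ok = x.notna() & b.notna()
        if ok.sum() < 3:
            skipped.append({"feature": feat, "reason": f"only {int(ok.sum())} complete pairs"})
            continue
        xv, bv = x[ok].to_numpy(), b[ok].to_numpy()
        if np.ptp(xv) == 0 or np.ptp(bv) == 0:
            skipped.append({"feature": feat, "reason": "constant values"})
            continue
        r = pearson_r(xv, bv)
        rng = _feature_seed(seed, feat, region, index_name)
        p = permutation_pvalue(bv, xv, B=B, seed=rng, sidedness=sidedness)
        tier = "q975" if p < 0.025 else ("q95" if p < 0.05 else "none")
        # least-squares line of feature on behavior index (for scatter panels)
        res = stats.linregress(bv, xv)
        results.append(
            ScreenResult(
                feature=feat, region=region, index=index_name,
                n_pairs=int(ok.sum()), r=r, r2=r * r, p_perm=p, tier=tier,
                slope=float(res.slope), intercept=float(res.intercept),
                slope_se=float(res.stderr),
            )
        )
    screen.last_skipped = skipped  # type: ignore[attr-defined]
    return results


def screen_frame(results: list[ScreenResult]) -> pd.DataFrame:
    """Tabular view of screen results with volcano coordinates."""
    df = pd.DataFrame([vars(r) for r in results])
    if len(df):
        df["neglog10_p"] = -np.log10(df["p_perm"])
    return df


@dataclass
class GroupTestResult:
    """Two-sample comparison of one feature between genotype groups."""

    feature: str
    region: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    df: float
    p: float
    variant: str
    note: str = ""


def _group_test(a, b, variant: str, feature: str = "", region: str = "") -> GroupTestResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    note = ""
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            t, df, p = 0.0, float(len(a) + len(b) - 2), 1.0
            note = "both groups constant and equal; p = 1 by convention"
        else:
            raise ConstantInputError("both groups constant with different means")
    elif variant == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        df = float((va / len(a) + vb / len(b)) ** 2 /
                   ((va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)))
    else:
        res = stats.ttest_ind(a, b, equal_var=True)
        t, p = float(res.statistic), float(res.pvalue)
        df = float(len(a) + len(b) - 2)
    return GroupTestResult(
        feature=feature, region=region, n_a=len(a), n_b=len(b),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(np.sqrt(va)), sd_b=float(np.sqrt(vb)),
        t=t, df=df, p=p, variant=variant, note=note,
    )


def welch_t_test(a, b, feature: str = "", region: str = "") -> GroupTestResult:
    """Two-tailed unpaired t-test with Welch's correction (Satterthwaite df)."""
    return _group_test(a, b, "welch", feature, region)


def student_t_test(a, b, feature: str = "", region: str = "") -> GroupTestResult:
    """Two-tailed unpaired Student t-test (pooled variance, df = n_a + n_b - 2)."""
    return _group_test(a, b, "student", feature, region)


def group_tests(
    features: pd.DataFrame,
    genotypes: pd.Series,
    region: str,
    variant: str = "welch",
) -> pd.DataFrame:
    """Per-feature genotype comparison over one region's feature columns."""
    sub = features.xs(region, level="region")
    g = genotypes.loc[genotypes.index.intersection(sub.index)]
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValueError("group_tests needs exactly two genotype groups")
    fn = welch_t_test if variant == "welch" else student_t_test
    rows = []
    for feat in sub.columns:
        a = sub.loc[g.index[g == levels[0]], feat].dropna()
        b = sub.loc[g.index[g == levels[1]], feat].dropna()
        if len(a) < 2 or len(b) < 2:
            continue
        try:
            res = fn(a, b, feature=feat, region=region)
        except ConstantInputError:
            continue
        rows.append(vars(res) | {"group_a": levels[0], "group_b": levels[1]})
    return pd.DataFrame(rows)
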