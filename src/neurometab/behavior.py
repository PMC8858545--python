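"""Three-chamber social behavior statistics.

The three-chamber assay scores how long a subject mouse investigates a
social target versus an alternative (an empty cup in the *preference*
session; a familiar conspecific in the *recognition* session).  The
per-animal summary is the preference index

    PI = (ET_target - ET_other) / (ET_target + ET_other)

which lies in [-1, 1]: +1 means exclusive investigation of the social
target, 0 no preference.  Session-level group comparisons use a 2x2
two-way ANOVA (genotype x target) with Sidak-corrected within-genotype
contrasts, the standard layout for this assay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PreferenceIndex",
    "UndefinedPIError",
    "compute_preference_index",
    "percent_investigation",
    "two_way_anova_sidak",
]


class UndefinedPIError(ValueError):
    """Raised when both exploration times are zero (PI is 0/0)."""


@dataclass(frozen=True)
class PreferenceIndex:
    """A preference index value for one animal and session."""

    value: float
    session: str = "preference"

    def __post_init__(self) -> None:
        if not -1.0 <= self.value <= 1.0:
            raise ValueError(f"preference index {self.value} outside [-1, 1]")


def compute_preference_index(et_target: float, et_other: float) -> float:
    """Preference index (ET_target - ET_other) / (ET_target + ET_other).

    Parameters
    ----------
    et_target : float
        Exploration time (seconds) for the social target (mouse / novel mouse).
    et_other : float
        Exploration time (seconds) for the alternative (empty cup / familiar mouse).

    Raises
    ------
    UndefinedPIError
        If both times are zero; the index is deliberately not coerced to 0,
        a no-exploration animal must be handled (excluded) explicitly.
    ValueError
        If either time is negative.
    """
    if et_target < 0 or et_other < 0:
        raise ValueError("exploration times must be non-negative")
    total = et_target + et_other
    if total == 0:
        raise UndefinedPIError("both exploration times are zero; PI undefined")
    return (et_target - et_other) / total


def percent_investigation(et_a: float, et_b: float) -> float:
    """Percentage of total investigation time spent on side *a*.

    Equals ``50 * (1 + PI(a, b))``; the two sides sum to 100.
    """
    if et_a < 0 or et_b < 0:
        raise ValueError("exploration times must be non-negative")
    total = et_a + et_b
    if total == 0:
        raise UndefinedPIError("both exploration times are zero; percentage undefined")
    return 100.0 * et_a / total


def two_way_anova_sidak(
    data: pd.DataFrame,
    value: str = "value",
    genotype: str = "genotype",
    target: str = "target",
) -> dict:
    """2x2 two-way ANOVA (genotype x target) with Sidak pairwise contrasts.

    Cell-mean / Type III decomposition with sum-to-zero contrasts, valid for
    unbalanced two-level factors, followed by within-genotype target
    contrasts using the pooled error mean square, with Sidak adjustment
    ``p_adj = 1 - (1 - p)^k`` over the k = 2 comparisons.

    Returns a dict with keys ``anova`` (DataFrame indexed by effect with
    columns F, df1, df2, p) and ``sidak`` (DataFrame of pairwise contrasts
    with t, df, p_raw, p_sidak).
    """
    df = data[[value, genotype, target]].dropna()
    glev = sorted(df[genotype].unique())
    tlev = sorted(df[target].unique())
    if len(glev) != 2 or len(tlev) != 2:
        raise ValueError("two_way_anova_sidak requires exactly two levels per factor")

    cells = {}
    for g in glev:
        for t in tlev:
            y = df.loc[(df[genotype] == g) & (df[target] == t), value].to_numpy(float)
            if len(y) < 2:
                raise ValueError(f"cell ({g}, {t}) has fewer than 2 observations")
            cells[(g, t)] = y

    n = {k: len(v) for k, v in cells.items()}
    m = {k: float(np.mean(v)) for k, v in cells.items()}
    N = sum(n.values())
    df_err = N - 4
    sse = sum(float(np.sum((v - m[k]) ** 2)) for k, v in cells.items())
    mse = sse / df_err

    # Type III via unweighted marginal means (sum-to-zero contrasts on a 2x2
    # grid); each effect is a single-df contrast of the four cell means.
    def contrast_ss(w: dict) -> float:
        est = sum(w[k] * m[k] for k in cells)
        var_unit = sum(w[k] ** 2 / n[k] for k in cells)
        return est**2 / var_unit

    g0, g1 = glev
    t0, t1 = tlev
    w_geno = {(g0, t0): 0.5, (g0, t1): 0.5, (g1, t0): -0.5, (g1, t1): -0.5}
    w_targ = {(g0, t0): 0.5, (g1, t0): 0.5, (g0, t1): -0.5, (g1, t1): -0.5}
    w_int = {(g0, t0): 1.0, (g0, t1): -1.0, (g1, t0): -1.0, (g1, t1): 1.0}

    rows = []
    for name, w in [(genotype, w_geno), (target, w_targ), ("interaction", w_int)]:
        F = contrast_ss(w) / mse if mse > 0 else 0.0
        p = float(stats.f.sf(F, 1, df_err)) if mse > 0 else 1.0
        rows.append({"effect": name, "F": F, "df1": 1, "df2": df_err, "p": p})
    anova = pd.DataFrame(rows).set_index("effect")

    k = 2  # one target contrast per genotype
    srows = []
    for g in glev:
        diff = m[(g, t0)] - m[(g, t1)]
        se = np.sqrt(mse * (1.0 / n[(g, t0)] + 1.0 / n[(g, t1)]))
        tval = diff / se if se > 0 else 0.0
        praw = float(2 * stats.t.sf(abs(tval), df_err))
        srows.append(
            {
                "genotype": g,
                "contrast": f"{t0} vs {t1}",
                "t": tval,
                "df": df_err,
                "p_raw": praw,
                "p_sidak": min(1.0, 1.0 - (1.0 - praw) ** k),
            }
        )
    return {"anova": anova, "sidak": pd.DataFrame(srows)}


def behavior_table(animals: pd.DataFrame) -> pd.DataFrame:
    """Per-animal preference indices from an exploration-time table.

    Expects long format with columns id, genotype, session, et_target,
    et_other (one row per animal per session).  Animals with zero total
    exploration in a session are excluded and listed in the ``excluded``
    attribute of the result (``result.attrs["excluded"]``).
    """
    rows, excluded = [], []
    for _, r in animals.iterrows():
        try:
            pi = compute_preference_index(r["et_target"], r["et_other"])
        except UndefinedPIError:
            excluded.append({"id": r["id"], "session": r["session"], "reason": "zero exploration"})
            continue
        rows.append(
            {
                "id": r["id"],
                "genotype": r["genotype"],
                "session": r["session"],
                "pi": pi,
                "pct_target": percent_investigation(r["et_target"], r["et_other"]),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["excluded"] = excluded
    return out
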