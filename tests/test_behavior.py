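"""Preference-index algebra and the 2x2 session ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neurometab.behavior import (
    UndefinedPIError,
    behavior_table,
    compute_preference_index,
    percent_investigation,
    two_way_anova_sidak,
)

times = st.floats(min_value=0.0, max_value=3600.0, allow_nan=False)


@pytest.mark.parametrize(
    "et_target,et_other,expected",
    [(120, 120, 0.0), (180, 60, 0.5), (0, 50, -1.0), (50, 0, 1.0), (600, 200, 0.5)],
)
def test_preference_index_values(et_target, et_other, expected):
    assert compute_preference_index(et_target, et_other) == pytest.approx(expected)


def test_zero_exploration_is_an_error_not_zero():
    with pytest.raises(UndefinedPIError):
        compute_preference_index(0.0, 0.0)
    with pytest.raises(ValueError):
        compute_preference_index(-1.0, 5.0)


@given(a=times, b=times)
@settings(max_examples=200, derandomize=True)
def test_pi_antisymmetry_and_percent_link(a, b):
    if a + b == 0:
        return
    pi = compute_preference_index(a, b)
    assert compute_preference_index(b, a) == pytest.approx(-pi, abs=1e-12)
    assert -1.0 <= pi <= 1.0
    # percentage view is an affine transform of the index
    assert percent_investigation(a, b) == pytest.approx(50.0 * (1.0 + pi), abs=1e-9)
    assert percent_investigation(a, b) + percent_investigation(b, a) == pytest.approx(100.0)


@given(a=times, b=times, k=st.floats(min_value=1e-3, max_value=1e3))
@settings(max_examples=200, derandomize=True)
def test_pi_scale_invariance(a, b, k):
    if a + b == 0:
        return
    assert compute_preference_index(k * a, k * b) == pytest.approx(
        compute_preference_index(a, b), abs=1e-9
    )


def _long_table(rng, means, n=(6, 6, 6, 6)):
    rows = []
    for (g, t, mu), ni in zip(
        [("WT", "target", means[0]), ("WT", "other", means[1]),
         ("KO", "target", means[2]), ("KO", "other", means[3])], n
    ):
        for v in mu + rng.normal(0, 1.0, ni):
            rows.append({"value": v, "genotype": g, "target": t})
    return pd.DataFrame(rows)


def test_anova_flat_data_gives_null_results(rng):
    df = _long_table(rng, [5, 5, 5, 5])
    df["value"] = 5.0  # identical cell means, zero within-cell noise
    df["value"] += np.tile([0.01, -0.01], len(df) // 2)  # minimal noise for MSE > 0
    res = two_way_anova_sidak(df)
    assert np.allclose(res["anova"]["F"], 0.0, atol=1e-20)
    assert np.allclose(res["sidak"]["p_sidak"], 1.0, atol=1e-12)


def test_anova_pure_interaction_pattern(rng):
    d = 3.0
    df = _long_table(rng, [d, -d, -d, d])
    res = two_way_anova_sidak(df)
    a = res["anova"]
    assert a.loc["interaction", "F"] > 10 * max(a.loc["genotype", "F"], a.loc["target", "F"])
    assert a.loc["interaction", "p"] < 0.01


def test_anova_matches_brute_force_and_statsmodels(rng):
    """F statistics agree with an independent sums-of-squares decomposition
    (balanced case) and with statsmodels Type III OLS (unbalanced case)."""
    df = _long_table(rng, [2.0, 0.5, -1.0, 1.5])
    res = two_way_anova_sidak(df)["anova"]

    # textbook balanced two-way SS decomposition
    piv = df.groupby(["genotype", "target"])["value"]
    cell_means = piv.mean()
    nc = 6
    grand = df["value"].mean()
    gm = cell_means.groupby("genotype").mean()
    tm = cell_means.groupby("target").mean()
    ss_a = 2 * nc * ((gm - grand) ** 2).sum()
    ss_b = 2 * nc * ((tm - grand) ** 2).sum()
    ss_int = nc * sum(
        (cell_means[g, t] - gm[g] - tm[t] + grand) ** 2
        for g in ("WT", "KO") for t in ("target", "other")
    )
    sse = sum(
        ((grp - grp.mean()) ** 2).sum() for _, grp in piv
    )
    mse = sse / (len(df) - 4)
    assert res.loc["genotype", "F"] == pytest.approx(ss_a / mse, abs=1e-10)
    assert res.loc["target", "F"] == pytest.approx(ss_b / mse, abs=1e-10)
    assert res.loc["interaction", "F"] == pytest.approx(ss_int / mse, abs=1e-10)

    # unbalanced layout: compare against statsmodels Type III
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df2 = _long_table(rng, [2.0, 0.5, -1.0, 1.5], n=(5, 8, 9, 6))
    res2 = two_way_anova_sidak(df2)["anova"]
    fit = smf.ols(
        "value ~ C(genotype, Sum) * C(target, Sum)", data=df2
    ).fit()
    tab = sm.stats.anova_lm(fit, typ=3)
    assert res2.loc["genotype", "F"] == pytest.approx(tab.loc["C(genotype, Sum)", "F"], rel=1e-8)
    assert res2.loc["target", "F"] == pytest.approx(tab.loc["C(target, Sum)", "F"], rel=1e-8)
    assert res2.loc["interaction", "F"] == pytest.approx(
        tab.loc["C(genotype, Sum):C(target, Sum)", "F"], rel=1e-8
    )


def test_sidak_adjustment_is_one_minus_power():
    rng = np.random.default_rng(5)
    df = _long_table(rng, [4.0, 1.0, 2.0, 2.0])
    sid = two_way_anova_sidak(df)["sidak"]
    for _, row in sid.iterrows():
        assert row["p_sidak"] == pytest.approx(1 - (1 - row["p_raw"]) ** 2, abs=1e-12)


def test_behavior_table_excludes_zero_exploration():
    animals = pd.DataFrame(
        [
            {"id": "A", "genotype": "WT", "session": "preference", "et_target": 300, "et_other": 100},
            {"id": "B", "genotype": "KO", "session": "preference", "et_target": 0, "et_other": 0},
        ]
    )
    out = behavior_table(animals)
    assert list(out["id"]) == ["A"]
    assert out.attrs["excluded"][0]["id"] == "B"
    assert out["pi"].iloc[0] == pytest.approx(0.5)
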