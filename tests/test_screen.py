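"""Pearson screen, permutation null, and two-sample group tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from neurometab.features import apply_crlb_filter, derive_features, metabolite_inclusion
from neurometab.behavior import behavior_table
from neurometab.screen import (
    ConstantInputError,
    InsufficientDataError,
    pearson_r,
    permutation_pvalue,
    screen,
    student_t_test,
    welch_t_test,
)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # cov = 3, sd_x = sd_y = sqrt(5) (n-1 denominators) -> r = 3/5
        assert pearson_r([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            pearson_r([1, 2], [3, 4])
        with pytest.raises(ConstantInputError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_pairwise_complete(self):
        x = [1, 2, np.nan, 4, 5]
        y = [2, 1, 7.0, 4, 3]
        assert pearson_r(x, y) == pytest.approx(pearson_r([1, 2, 4, 5], [2, 1, 4, 3]))


class TestPermutation:
    def test_perfect_correlation_hits_floor(self):
        x = np.arange(10.0)
        B = 999
        p = permutation_pvalue(x, x, B=B, seed=1)
        assert p == pytest.approx(1 / (B + 1))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=15), rng.normal(size=15)
        assert permutation_pvalue(x, y, B=500, seed=11) == permutation_pvalue(
            x, y, B=500, seed=11
        )

    def test_exhaustive_matches_bruteforce_oracle(self):
        """The fast enumeration path equals a direct loop over all n! pairings."""
        from itertools import permutations

        rng = np.random.default_rng(8)
        x = rng.normal(size=6)
        y = 0.5 * x + rng.normal(size=6)
        r_obs = abs(pearson_r(x, y))
        count = total = 0
        for perm in permutations(range(6)):
            r = np.corrcoef(x, y[list(perm)])[0, 1]
            count += abs(r) >= r_obs - 1e-14
            total += 1
        assert permutation_pvalue(x, y, method="exhaustive") == pytest.approx(count / total)

    def test_affine_invariance_and_sign_symmetry(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=12), rng.normal(size=12)
        p0 = permutation_pvalue(x, y, B=300, seed=5)
        assert permutation_pvalue(3 * x - 1, 0.5 * y + 7, B=300, seed=5) == pytest.approx(p0)
        assert permutation_pvalue(x, -y, B=300, seed=5) == pytest.approx(p0)

    def test_one_sided_modes(self):
        x = np.arange(8.0)
        y = x + np.random.default_rng(0).normal(0, 0.5, 8)
        pg = permutation_pvalue(x, y, method="exhaustive", sidedness="greater")
        pl = permutation_pvalue(x, y, method="exhaustive", sidedness="less")
        assert pg < 0.05 < pl

    def test_bad_args(self):
        with pytest.raises(ValueError):
            permutation_pvalue([1, 2, 3, 4], [1, 2, 3, 4], B=0, seed=1)
        with pytest.raises(ValueError):
            permutation_pvalue([1, 2, 3, 4], [4, 3, 2, 1], sidedness="weird")


class TestScreen:
    def test_planted_signal_selected(self, default_cohort):
        animals, measurements, _ = default_cohort
        filtered = apply_crlb_filter(measurements)
        genotypes = animals.drop_duplicates("id").set_index("id")["genotype"]
        inc = metabolite_inclusion(filtered, genotypes)
        feats = derive_features(filtered)
        bt = behavior_table(animals)
        pi = bt[bt["session"] == "preference"].set_index("id")["pi"]
        res = screen(feats, pi, "PFC", "preference", B=2000, seed=9, included=inc)
        byname = {r.feature: r for r in res}
        assert byname["Glu/GABA"].tier in ("q95", "q975")
        assert byname["Glu/GABA"].r > 0
        assert byname["GABA/Glu"].r < 0  # reciprocal flips the sign
        for r in res:
            assert -1 <= r.r <= 1
            assert r.p_perm >= 1 / 2001
            assert r.r2 == pytest.approx(r.r**2)
            if r.tier == "q975":
                assert r.p_perm < 0.025 < 0.05

    def test_screen_results_order_independent(self, default_cohort):
        """Per-(feature, index) RNG streams: dropping a column leaves others unchanged."""
        animals, measurements, _ = default_cohort
        feats = derive_features(apply_crlb_filter(measurements))
        bt = behavior_table(animals)
        pi = bt[bt["session"] == "preference"].set_index("id")["pi"]
        full = {r.feature: r.p_perm for r in screen(feats, pi, "PFC", "preference", B=400, seed=1)}
        subset = feats.drop(columns=["NAA", "Tau"])
        part = {r.feature: r.p_perm for r in screen(subset, pi, "PFC", "preference", B=400, seed=1)}
        for k, v in part.items():
            assert full[k] == pytest.approx(v)

    def test_no_overlap_errors(self, default_cohort):
        import pandas as pd

        _, measurements, _ = default_cohort
        feats = derive_features(apply_crlb_filter(measurements))
        foreign = pd.Series([0.1, 0.2], index=["X1", "X2"])
        with pytest.raises(ValueError, match="overlap"):
            screen(feats, foreign, "PFC", "preference", B=10, seed=0)


class TestGroupTests:
    def test_identical_groups(self):
        r = welch_t_test([1.0, 2, 3], [1.0, 2, 3])
        assert r.t == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_clear_separation(self):
        r = welch_t_test([1.0, 2, 3], [11.0, 12, 13])
        assert r.t < -5
        assert r.p < 0.01

    def test_welch_matches_reference(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(4, 12))
            b = rng.normal(0.5, 2, rng.integers(4, 12))
            ours = welch_t_test(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert ours.t == pytest.approx(float(ref.statistic), abs=1e-10)
            assert ours.p == pytest.approx(float(ref.pvalue), abs=1e-10)
            # Satterthwaite df is fractional and between min(n)-1 and n_a+n_b-2
            assert min(len(a), len(b)) - 1 <= ours.df <= len(a) + len(b) - 2

    def test_welch_equals_student_for_equal_n_equal_var(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        b = (b - b.mean()) / b.std(ddof=1) * a.std(ddof=1) + b.mean()  # equalize variances
        w, s = welch_t_test(a, b), student_t_test(a, b)
        assert w.t == pytest.approx(s.t, abs=1e-10)
        assert w.df == pytest.approx(s.df, abs=1e-8)

    def test_degenerate_and_errors(self):
        r = welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert r.p == 1.0 and "convention" in r.note
        with pytest.raises(InsufficientDataError):
            welch_t_test([1.0], [1.0, 2.0])


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=30, derandomize=True, deadline=None)
def test_permutation_p_within_bounds(seed):
    rng = np.random.default_rng(seed)
    x, y = rng.normal(size=10), rng.normal(size=10)
    B = 199
    p = permutation_pvalue(x, y, B=B, seed=seed)
    assert 1 / (B + 1) <= p <= 1.0
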