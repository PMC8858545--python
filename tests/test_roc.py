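"""Logistic fit and binormal ROC: closed forms, oracles, invariances."""

import numpy as np
import pytest
from scipy import stats

from neurometab.roc import (
    binormal_roc,
    empirical_auc,
    fit_simple_logistic,
    hanley_mcneil_se,
    optimal_cutoff,
)


class TestLogistic:
    def test_uninformative_feature(self):
        x = np.array([1.0, 1, 1, 1, 1, 1])
        y = np.array([0, 0, 1, 1, 1, 1])
        fit = fit_simple_logistic(x, y)
        assert fit.slope == 0.0
        assert fit.predict([1.0])[0] == pytest.approx(y.mean())

    def test_two_support_closed_form(self):
        # x in {0, 1}; with overlap the MLE is the empirical log-odds at each point
        x = np.array([0.0] * 10 + [1.0] * 10)
        y = np.array([0] * 8 + [1] * 2 + [0] * 3 + [1] * 7)
        fit = fit_simple_logistic(x, y)
        lo0 = np.log((2 / 10) / (8 / 10))
        lo1 = np.log((7 / 10) / (3 / 10))
        assert fit.intercept == pytest.approx(lo0, abs=1e-6)
        assert fit.intercept + fit.slope == pytest.approx(lo1, abs=1e-6)
        assert fit.converged and not fit.separated

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        x = rng.normal(size=40)
        y = (rng.random(40) < 1 / (1 + np.exp(-(0.3 + 1.2 * x)))).astype(int)
        ours = fit_simple_logistic(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert ours.intercept == pytest.approx(ref.params[0], abs=1e-6)
        assert ours.slope == pytest.approx(ref.params[1], abs=1e-6)

    def test_affine_rescaling(self, rng):
        x = rng.normal(size=30)
        y = (x + rng.normal(0, 1, 30) > 0).astype(int)
        f1 = fit_simple_logistic(x, y)
        f2 = fit_simple_logistic(10 * x, y)
        assert f2.slope == pytest.approx(f1.slope / 10, rel=1e-5)
        assert np.allclose(f1.predict(x), f2.predict(10 * x), atol=1e-6)

    def test_separation_flagged_not_divergent(self):
        x = np.array([0.0, 1, 2, 3, 10, 11, 12, 13])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        fit = fit_simple_logistic(x, y)
        assert fit.separated
        assert np.isfinite(fit.slope) and np.isfinite(fit.intercept)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            fit_simple_logistic([1.0, 2, 3, 4], [1, 1, 1, 1])


class TestBinormal:
    def test_no_separation_gives_half(self, rng):
        neg = rng.normal(0, 1, 200)
        pos = neg + 0.0
        r = binormal_roc(neg, pos)
        assert r.auc == pytest.approx(0.5, abs=1e-12)

    def test_unit_separation_closed_form(self):
        # construct samples whose moments are exactly mu0=0, s0=s1=1, mu1=sqrt(2)
        base = np.array([-1.5, -0.5, 0.5, 1.5])
        base = (base - base.mean()) / base.std(ddof=1)
        r = binormal_roc(base, base + np.sqrt(2.0))
        assert r.auc == pytest.approx(stats.norm.cdf(1.0), abs=1e-12)

    def test_closed_form_vs_empirical_large_sample(self, rng):
        neg = rng.normal(0, 1, 100_000)
        pos = rng.normal(np.sqrt(1 + 1.5**2), 1.5, 100_000)
        r = binormal_roc(neg, pos)
        emp = empirical_auc(neg, pos)
        assert abs(r.auc - stats.norm.cdf(1.0)) < 0.01
        assert abs(emp - r.auc) < 0.01

    def test_label_swap_complements_auc(self, rng):
        neg = rng.normal(0, 1, 50)
        pos = rng.normal(1.2, 1.4, 60)
        r = binormal_roc(neg, pos)
        swapped = binormal_roc(pos, neg)
        assert swapped.auc == pytest.approx(1 - r.auc, abs=1e-12)

    def test_auc_invariant_under_logistic_transform(self, rng):
        """Empirical AUC is unchanged by any monotone score transform."""
        neg = rng.normal(0, 1, 40)
        pos = rng.normal(1, 1.3, 40)
        from scipy.special import expit

        assert empirical_auc(neg, pos) == pytest.approx(
            empirical_auc(expit(0.7 * neg - 1), expit(0.7 * pos - 1)), abs=1e-12
        )

    def test_hanley_mcneil_ci(self, rng):
        neg = rng.normal(0, 1, 11)
        pos = rng.normal(1.5, 1, 9)
        r = binormal_roc(neg, pos)
        se = hanley_mcneil_se(r.auc, 11, 9)
        assert r.auc_ci_low == pytest.approx(max(0, r.auc - 1.959963984540054 * se))
        assert r.auc_ci_low <= r.auc <= r.auc_ci_high <= 1.0

    def test_bootstrap_ci_close_to_hanley(self, rng):
        neg = rng.normal(0, 1, 30)
        pos = rng.normal(1.2, 1, 30)
        hm = binormal_roc(neg, pos)
        bs = binormal_roc(neg, pos, ci_method="bootstrap", n_boot=1000, seed=5)
        assert bs.auc == pytest.approx(hm.auc)
        assert abs((bs.auc_ci_high - bs.auc_ci_low) - (hm.auc_ci_high - hm.auc_ci_low)) < 0.12

    def test_degenerate_errors(self):
        with pytest.raises(ValueError):
            binormal_roc([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            binormal_roc([1.0], [0.0, 2.0])

    def test_curve_is_valid_roc(self, rng):
        r = binormal_roc(rng.normal(0, 1, 30), rng.normal(1, 2, 30))
        fpr, tpr = r.curve[:, 0], r.curve[:, 1]
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)
        assert fpr[0] < 0.01 and fpr[-1] > 0.99


class TestCutoff:
    def test_equal_variance_midpoint(self):
        base = np.array([-1.0, -0.5, 0.5, 1.0])
        r = binormal_roc(base, base + 2.0)
        assert r.cutoff == pytest.approx(1.0, abs=1e-12)  # (mu0 + mu1) / 2

    def test_matches_grid_oracle(self, rng):
        neg = rng.normal(0, 1.0, 200)
        pos = rng.normal(1.8, 2.1, 200)
        r = binormal_roc(neg, pos)
        grid = np.linspace(min(neg.min(), pos.min()), max(neg.max(), pos.max()), 10_000)
        J = (stats.norm.cdf((r.mu1 - grid) / r.sigma1)
             - stats.norm.cdf((r.mu0 - grid) / r.sigma0))
        c_grid = grid[np.argmax(J)]
        assert abs(r.cutoff - c_grid) < (grid[1] - grid[0]) * 2
        cut, sens, spec = optimal_cutoff(r)
        assert sens + spec - 100 == pytest.approx(100 * J.max(), abs=0.1)

    def test_degenerate_zero_J(self, rng):
        neg = rng.normal(0, 1, 100)
        r = binormal_roc(neg, neg.copy())
        assert r.degenerate
        _, sens, spec = optimal_cutoff(r)
        assert sens + spec - 100 == pytest.approx(0.0, abs=1e-9)

    def test_auto_flip(self, rng):
        neg = rng.normal(2.0, 1, 50)  # negatives higher: raw AUC < 0.5
        pos = rng.normal(0.0, 1, 50)
        raw = binormal_roc(neg, pos)
        flipped = binormal_roc(neg, pos, auto_flip=True)
        assert raw.auc < 0.5 < flipped.auc
        assert flipped.flipped
        assert flipped.auc == pytest.approx(1 - raw.auc, abs=1e-12)
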