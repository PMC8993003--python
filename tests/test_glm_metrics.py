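"""Logistic IRLS fitter and the evaluation-metric suite."""

import numpy as np
import pytest
from scipy import optimize, stats

from ctprs.glm import RankDeficiencyError, SeparationError, fit_logistic
from ctprs.metrics import auc, hosmer_lemeshow, pseudo_r2, s80

from .oracles import auc_all_pairs, logistic_loglik, s80_threshold_scan


class TestFitLogistic:
    def test_2x2_saturated_closed_form(self):
        # counts: a=30 (x=1,y=1), b=20 (x=1,y=0), c=10 (x=0,y=1), d=40 (x=0,y=0)
        a, b, c, d = 30, 20, 10, 40
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        fit = fit_logistic(np.column_stack([np.ones_like(x), x]), y, ["c", "x"])
        assert fit.params[1] == pytest.approx(np.log(a * d / (b * c)), abs=1e-8)
        assert fit.params[0] == pytest.approx(np.log(c / d), abs=1e-8)

    def test_intercept_only_is_logit_of_case_fraction(self):
        y = np.r_[np.ones(13), np.zeros(87)]
        fit = fit_logistic(np.ones((100, 1)), y, ["c"])
        assert fit.params[0] == pytest.approx(np.log(0.13 / 0.87), abs=1e-8)

    def test_gradient_zero_and_matches_generic_optimizer(self, rng):
        X = np.column_stack([np.ones(50), rng.normal(size=(50, 2))])
        beta_true = np.array([-0.5, 0.8, -0.3])
        y = (rng.uniform(size=50) < 1 / (1 + np.exp(-X @ beta_true))).astype(float)
        fit = fit_logistic(X, y, ["c", "x1", "x2"])
        mu = 1 / (1 + np.exp(-X @ fit.params))
        grad = X.T @ (y - mu)
        assert np.abs(grad).max() < 1e-6
        res = optimize.minimize(
            lambda b: -logistic_loglik(b, X, y), np.zeros(3), method="BFGS",
            options={"gtol": 1e-10},
        )
        np.testing.assert_allclose(fit.params, res.x, atol=1e-6)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        X = np.column_stack([np.ones(120), rng.normal(size=(120, 3))])
        y = (rng.uniform(size=120) < 0.3).astype(float)
        fit = fit_logistic(X, y)
        smf = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.params, smf.params, atol=1e-6)
        np.testing.assert_allclose(fit.bse, smf.bse, rtol=1e-4)
        assert fit.loglik == pytest.approx(smf.llf, abs=1e-8)

    def test_perfect_separation_raises(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        with pytest.raises(SeparationError):
            fit_logistic(np.column_stack([np.ones(40), x]), y, ["c", "x"])

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=60)
        X = np.column_stack([np.ones(60), x, 2 * x])
        y = (rng.uniform(size=60) < 0.4).astype(float)
        # either member of the collinear pair may be flagged
        with pytest.raises(RankDeficiencyError, match="x|dup"):
            fit_logistic(X, y, ["c", "x", "dup"])


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_no_separation(self):
        assert auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_six_observation_toy_vs_all_pairs(self):
        p = [0.1, 0.4, 0.35, 0.8, 0.8, 0.2]
        y = [0, 0, 1, 1, 0, 1]
        assert auc(p, y) == pytest.approx(auc_all_pairs(p, y), abs=1e-12)

    def test_random_instances_vs_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 20))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            p = np.round(rng.uniform(size=n), 2)  # rounding forces ties
            assert auc(p, y) == pytest.approx(auc_all_pairs(p, y), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        p = rng.uniform(size=40)
        y = rng.integers(0, 2, 40)
        if y.sum() in (0, 40):
            y[0] = 1 - y[0]
        assert auc(p, y) == pytest.approx(auc(1 / (1 + np.exp(-5 * p)), y), abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


class TestS80:
    def test_perfect_classifier(self):
        assert s80([0.9, 0.8, 0.1, 0.2, 0.15], [1, 1, 0, 0, 0]) == 1.0

    def test_uninformative_scores(self):
        assert s80([0.3] * 10, [1, 0] * 5) == 0.0

    def test_ten_observation_toy_vs_scan_oracle(self):
        p = [0.05, 0.1, 0.2, 0.3, 0.42, 0.42, 0.55, 0.6, 0.77, 0.9]
        y = [0, 0, 0, 1, 0, 1, 0, 1, 1, 1]
        assert s80(p, y) == pytest.approx(s80_threshold_scan(p, y), abs=1e-12)

    def test_random_instances_vs_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 40))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            p = np.round(rng.uniform(size=n), 2)
            assert s80(p.tolist(), y.tolist()) == pytest.approx(
                s80_threshold_scan(p.tolist(), y.tolist()), abs=1e-12
            )


class TestPseudoR2:
    def test_no_improvement_is_zero(self):
        assert pseudo_r2(-40.0, -40.0, 100) == 0.0

    def test_perfect_fit_is_one(self):
        ll_null = 50 * np.log(0.5)
        assert pseudo_r2(0.0, ll_null, 50) == pytest.approx(1.0, abs=1e-12)

    def test_worked_example_matches_formula(self):
        ll_full, ll_null, n = -8.2, -12.9, 20
        cs = 1 - np.exp(2 * (ll_null - ll_full) / n)
        expect = cs / (1 - np.exp(2 * ll_null / n))
        assert pseudo_r2(ll_full, ll_null, n) == pytest.approx(expect, abs=1e-10)
        assert pseudo_r2(ll_full, ll_null, n, kind="cox-snell") == pytest.approx(
            cs, abs=1e-10
        )
        assert pseudo_r2(ll_full, ll_null, n, kind="mcfadden") == pytest.approx(
            1 - ll_full / ll_null, abs=1e-10
        )


class TestHosmerLemeshow:
    def test_perfect_calibration_statistic_zero(self):
        # fitted probabilities exactly equal to group case rates
        p = np.repeat([0.1, 0.2, 0.3, 0.4, 0.5], 20)
        rng = np.random.default_rng(0)
        y = np.concatenate([
            np.r_[np.ones(int(q * 20)), np.zeros(20 - int(q * 20))]
            for q in (0.1, 0.2, 0.3, 0.4, 0.5)
        ])
        stat, pval = hosmer_lemeshow(p, y, g=5)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert pval == 1.0

    def test_twenty_observation_toy_matches_hand_computation(self):
        rng = np.random.default_rng(42)
        p = np.sort(rng.uniform(0.05, 0.95, 20))
        y = (rng.uniform(size=20) < p).astype(float)
        stat, _ = hosmer_lemeshow(p, y, g=4)
        # hand computation with the same grouping rule (5 per group, no ties)
        expect = 0.0
        for k in range(4):
            sl = slice(5 * k, 5 * (k + 1))
            O, E, n_g = y[sl].sum(), p[sl].sum(), 5
            expect += (O - E) ** 2 / (E * (1 - E / n_g))
        assert stat == pytest.approx(expect, abs=1e-10)

    def test_null_rejection_rate_calibrated(self):
        """Well-specified logistic model: HL rejects at ~5%."""
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 300
        for _ in range(reps):
            x = rng.normal(size=500)
            p_true = 1 / (1 + np.exp(-(-1.0 + 0.8 * x)))
            y = (rng.uniform(size=500) < p_true).astype(float)
            fit = fit_logistic(np.column_stack([np.ones(500), x]), y, ["c", "x"])
            _, pval = hosmer_lemeshow(fit.fitted, y, g=10)
            if pval < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.03)
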