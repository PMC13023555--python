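"""Regularized LDA, nested CV, and the resampling evaluation suite."""

import itertools

import numpy as np
import pytest

from t2oa.classify_eval import (
    CVConfig,
    bootstrap_auc_ci,
    calibration_brier,
    decision_curve,
    delong_test,
    fit_rlda,
    nested_cv,
    permutation_test_auc,
    roc_auc,
    weight_stability,
)

FAST_CV = CVConfig(outer_folds=5, inner_folds=3, repeats=2, lambda_grid=(0.1, 0.5, 0.9))


def _gaussian_two_class(rng, n_per=26, p=5, delta=0.0):
    X = rng.normal(0, 1, (2 * n_per, p))
    y = np.repeat([0, 1], n_per)
    X[y == 1, 0] += delta
    ages = rng.uniform(40, 75, 2 * n_per)
    return X, y, ages


class TestFitRlda:
    def test_full_shrinkage_direction_is_mean_difference(self, rng):
        X, y, _ = _gaussian_two_class(rng, 20, 6, 1.0)
        m = fit_rlda(X, y, 1.0)
        d = X[y == 1].mean(0) - X[y == 0].mean(0)
        cos = m.weights @ d / (np.linalg.norm(m.weights) * np.linalg.norm(d))
        assert cos == pytest.approx(1.0, abs=1e-12)

    def test_label_swap_negates_weights(self, rng):
        X, y, _ = _gaussian_two_class(rng, 15, 4, 0.5)
        m1 = fit_rlda(X, y, 0.3)
        m2 = fit_rlda(X, 1 - y, 0.3)
        np.testing.assert_allclose(m2.weights, -m1.weights, atol=1e-12)
        np.testing.assert_allclose(m2.intercept, -m1.intercept, atol=1e-12)

    def test_two_feature_hand_linear_system(self):
        # 2 features, 4+4 samples: solve S_pooled w = mu1 - mu0 by hand
        X0 = np.array([[0.0, 0.0], [1.0, 0.5], [0.5, 1.0], [1.5, 1.5]])
        X1 = X0 + np.array([2.0, 1.0])
        X = np.vstack([X0, X1])
        y = np.repeat([0, 1], 4)
        lam = 0.2
        C0 = X0 - X0.mean(0)
        C1 = X1 - X1.mean(0)
        S = (C0.T @ C0 + C1.T @ C1) / 6
        Sh = (1 - lam) * S + lam * (np.trace(S) / 2) * np.eye(2)
        expected = np.linalg.solve(Sh, X1.mean(0) - X0.mean(0))
        m = fit_rlda(X, y, lam)
        np.testing.assert_allclose(m.weights, expected, atol=1e-12)

    def test_singular_unregularized_raises_with_advice(self, rng):
        X = rng.normal(0, 1, (8, 20))  # p > n: singular at lam = 0
        y = np.repeat([0, 1], 4)
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage > 0"):
            fit_rlda(X, y, 0.0)

    def test_posteriors_in_unit_interval(self, rng):
        X, y, _ = _gaussian_two_class(rng, 10, 3, 2.0)
        m = fit_rlda(X, y, 0.5)
        p = m.posteriors(X)
        assert np.all((p >= 0) & (p <= 1))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_all_tied_is_half(self):
        assert roc_auc(np.ones(8), [0, 1] * 4) == 0.5

    def test_six_point_brute_force(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.35, 0.9])
        labels = np.array([0, 0, 1, 1, 0, 1])
        wins = 0.0
        for i, j in itertools.product(range(6), range(6)):
            if labels[i] == 1 and labels[j] == 0:
                wins += (scores[i] > scores[j]) + 0.5 * (scores[i] == scores[j])
        assert roc_auc(scores, labels) == pytest.approx(wins / 9, abs=1e-12)

    def test_auc_u_duality_property(self, rng):
        for _ in range(20):
            s = rng.normal(0, 1, 30).round(1)  # rounding forces ties
            y = rng.integers(0, 2, 30)
            if y.sum() in (0, 30):
                continue
            n1, n0 = y.sum(), 30 - y.sum()
            wins = sum(
                (a > b) + 0.5 * (a == b)
                for a in s[y == 1]
                for b in s[y == 0]
            )
            assert roc_auc(s, y) * n1 * n0 == pytest.approx(wins, abs=1e-9)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])


class TestNestedCv:
    def test_fixed_seed_bit_identical(self, rng):
        X, y, ages = _gaussian_two_class(rng, 26, 6, 1.0)
        a = nested_cv(X, y, FAST_CV, seed=11, ages=ages)
        b = nested_cv(X, y, FAST_CV, seed=11, ages=ages)
        np.testing.assert_array_equal(a.oof_scores, b.oof_scores)
        np.testing.assert_array_equal(a.fold_weights, b.fold_weights)

    def test_informative_feature_high_auc(self):
        # one feature separated by 2 SD: analytic AUC = Phi(2/sqrt(2)) ~ 0.92.
        # With 26 per group the realized separation itself fluctuates (SD of
        # the mean difference ~ 0.28), so even the Bayes-optimal rule drops
        # below 0.85 in a few percent of draws; require 18/20 fixed draws.
        cfg = CVConfig(
            outer_folds=5, inner_folds=3, repeats=2,
            lambda_grid=(0.1, 0.5, 0.9), adjust_age=False,
        )
        hits = 0
        aucs = []
        for rep in range(20):
            X, y, _ = _gaussian_two_class(
                np.random.default_rng(100 + rep), 26, 1, 2.0
            )
            cv = nested_cv(X, y, cfg, seed=rep)
            aucs.append(cv.mean_auc)
            hits += cv.mean_auc > 0.85
        assert hits >= 18
        assert np.mean(aucs) > 0.85

    def test_no_leakage_corrupting_test_labels(self, rng):
        # with the fold structure held fixed, flipping held-out labels must
        # not change that fold's scores
        X, y, ages = _gaussian_two_class(rng, 15, 4, 1.0)
        idx = np.arange(len(y))
        splits = [
            (idx[idx % 3 != k], idx[idx % 3 == k]) for k in range(3)
        ]
        cfg = CVConfig(repeats=1, inner_folds=3, outer_folds=3)
        ref = nested_cv(X, y, cfg, seed=5, ages=ages, outer_splits=splits)
        te = splits[0][1]
        y2 = y.copy()
        y2[te] = 1 - y2[te]
        alt = nested_cv(X, y2, cfg, seed=5, ages=ages, outer_splits=splits)
        np.testing.assert_allclose(
            ref.oof_scores[0, te], alt.oof_scores[0, te], atol=1e-10
        )

    def test_every_subject_scored_once(self, rng):
        X, y, ages = _gaussian_two_class(rng, 13, 3, 0.5)
        cv = nested_cv(X, y, FAST_CV, seed=1, ages=ages)
        assert np.all(np.isfinite(cv.oof_scores))
        assert cv.oof_scores.shape == (FAST_CV.repeats, len(y))


class TestBootstrapPermutation:
    def test_perfect_separation_ci_degenerate(self):
        s = np.array([0, 0, 0, 1, 1, 1.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        lo, hi = bootstrap_auc_ci(s, y, n_boot=200, seed=1)
        assert lo == 1.0 and hi == 1.0

    def test_ci_seed_reproducible(self, rng):
        s = rng.normal(0, 1, 40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        assert bootstrap_auc_ci(s, y, 100, seed=9) == bootstrap_auc_ci(s, y, 100, seed=9)

    def test_ci_contains_point_estimate(self, rng):
        for rep in range(20):
            r = np.random.default_rng(rep)
            s = r.normal(0, 1, 30) + r.integers(0, 2, 30)
            y = np.repeat([0, 1], 15)
            s = r.normal(y.astype(float), 1.0)
            lo, hi = bootstrap_auc_ci(s, y, 400, seed=rep)
            assert lo - 1e-12 <= roc_auc(s, y) <= hi + 1e-12

    def test_permutation_p_lower_bound(self, rng):
        X, y, ages = _gaussian_two_class(rng, 13, 2, 3.0)
        cfg = CVConfig(repeats=1, inner_folds=3, lambda_grid=(0.5,))
        _, p, null = permutation_test_auc(X, y, cfg, n_perm=19, seed=2, ages=ages)
        assert p >= 1 / 20 - 1e-12
        assert len(null) == 19


class TestDelong:
    def test_identical_scores_p_one(self, rng):
        s = rng.normal(0, 1, 30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        diff, p = delong_test(s, s, y)
        assert diff == 0.0 and p == 1.0

    def test_antisymmetric(self, rng):
        a = rng.normal(0, 1, 24)
        b = rng.normal(0, 1, 24)
        y = np.repeat([0, 1], 12)
        d1, p1 = delong_test(a, b, y)
        d2, p2 = delong_test(b, a, y)
        assert d1 == pytest.approx(-d2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_placement_variance_oracle_ten_subjects(self):
        # independent double-loop re-derivation of the structural components
        a = np.array([0.1, 0.9, 0.3, 0.7, 0.5, 0.2, 0.8, 0.4, 0.6, 0.55])
        b = np.array([0.2, 0.8, 0.1, 0.9, 0.4, 0.3, 0.6, 0.5, 0.7, 0.45])
        y = np.array([0, 1, 0, 1, 0, 0, 1, 0, 1, 1])
        pos, neg = np.where(y == 1)[0], np.where(y == 0)[0]
        m, n = len(pos), len(neg)

        def placements(s):
            v10 = [np.mean([(s[i] > s[j]) + 0.5 * (s[i] == s[j]) for j in neg]) for i in pos]
            v01 = [np.mean([(s[i] > s[j]) + 0.5 * (s[i] == s[j]) for i in pos]) for j in neg]
            return np.array(v10), np.array(v01)

        va10, va01 = placements(a)
        vb10, vb01 = placements(b)
        s10 = np.cov(np.stack([va10, vb10]))
        s01 = np.cov(np.stack([va01, vb01]))
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
            s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
        ) / n
        diff = va10.mean() - vb10.mean()
        from scipy.stats import norm

        expected_p = 2 * norm.sf(abs(diff / np.sqrt(var)))
        got_diff, got_p = delong_test(a, b, y)
        assert got_diff == pytest.approx(diff, abs=1e-8)
        assert got_p == pytest.approx(expected_p, abs=1e-8)


class TestCalibrationDecision:
    def test_perfect_posteriors_brier_zero(self):
        y = np.array([0, 1, 0, 1])
        *_, brier = calibration_brier(y.astype(float), y)
        assert brier == 0.0

    def test_constant_half_brier_quarter(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        *_, brier = calibration_brier(np.full(6, 0.5), y)
        assert brier == pytest.approx(0.25)

    def test_hand_computed_four_subjects(self):
        p = np.array([0.2, 0.9, 0.6, 0.4])
        y = np.array([0, 1, 1, 0])
        *_, brier = calibration_brier(p, y)
        expected = (0.04 + 0.01 + 0.16 + 0.16) / 4
        assert brier == pytest.approx(expected, abs=1e-12)

    def test_treat_none_zero_everywhere(self, rng):
        p = rng.uniform(0, 1, 30)
        y = rng.integers(0, 2, 30)
        _, _, _, nb_none = decision_curve(p, y)
        assert np.all(nb_none == 0)

    def test_treat_all_zero_at_prevalence_threshold(self):
        y = np.repeat([0, 1], 10)  # prevalence 0.5
        thr, _, nb_all, _ = decision_curve(np.full(20, 0.5), y, thresholds=np.array([0.5]))
        assert nb_all[0] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_classifier_net_benefit_is_prevalence(self):
        y = np.repeat([0, 1], 13)
        p = y.astype(float)
        thr, nb, *_ = decision_curve(p, y, thresholds=np.arange(0.1, 0.91, 0.1))
        np.testing.assert_allclose(nb, y.mean(), atol=1e-12)


class TestWeightStability:
    def test_constant_weights_zero_variance(self):
        W = np.tile([1.0, -2.0, 0.5], (8, 1))
        stab = weight_stability(W)
        np.testing.assert_allclose(stab.sd, 0.0, atol=1e-15)
        assert np.all(np.isinf(stab.stat))

    def test_informative_feature_ranks_first(self):
        hits = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            X, y, ages = _gaussian_two_class(r, 26, 5, 0.0)
            X[y == 1, 2] += 2.0  # feature 2 informative
            cv = nested_cv(X, y, FAST_CV, seed=rep, ages=ages)
            stab = weight_stability(cv.fold_weights)
            hits += np.argmax(stab.stat) == 2
        assert hits >= 18

    def test_noise_features_sign_flip_near_chance(self):
        r = np.random.default_rng(0)
        X, y, ages = _gaussian_two_class(r, 26, 6, 0.0)
        cv = nested_cv(X, y, FAST_CV, seed=0, ages=ages)
        signs = np.mean(cv.fold_weights > 0, axis=0)
        # pure-noise weights: sign consistency should not be extreme overall
        assert 0.15 < signs.mean() < 0.85
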