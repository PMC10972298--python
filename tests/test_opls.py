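import numpy as np
import pytest
from sklearn.metrics import auc as sk_auc

from urinmr.opls import (
    _fit_opls_core,
    cross_validated_scores,
    fit_opls_da,
    permutation_test,
    q2_cv,
    roc_from_scores,
)
from urinmr.simulate import simulate_paired_features
from urinmr.viavc import _pls1_predict, auc_concordance


def _two_class_data(seed=0, n=20, p=6, sep=2.0, ortho_sd=0.0):
    rng = np.random.default_rng(seed)
    y = np.repeat([1.0, -1.0], n // 2)
    X = rng.normal(size=(n, p))
    X[:, 0] += sep * y / 2.0
    if ortho_sd:
        X[:, 1] += ortho_sd * rng.normal(size=n)
    return X, y


class TestFit:
    def test_zero_orthogonal_equals_pls1_scores(self):
        X, y = _two_class_data(seed=1)
        model = _fit_opls_core(X, y, n_orth=0)
        # one-component PLS1 fitted values on the training data
        pls1 = _pls1_predict(X, y, X, 1)
        np.testing.assert_allclose(model.t_pred * model.q_pred + model.y_mean,
                                   pls1, rtol=1e-10)

    def test_orthogonal_component_isolates_class_independent_variation(self):
        # noise-free geometry: predictive structure y along e1, large
        # class-independent variation z along (e1+e2)/sqrt(2).  The single
        # orthogonal weight must come out as e2: the part of the overlapping
        # structured variation that carries no class information.
        rng = np.random.default_rng(2)
        n = 40
        y = np.repeat([1.0, -1.0], n // 2)
        z = 8.0 * rng.normal(size=n)
        z = z - (z @ y) / (y @ y) * y  # strictly class-independent in sample
        v = np.array([1.0, 1.0]) / np.sqrt(2)
        X = np.outer(y, [1.0, 0.0]) + np.outer(z, v)
        model = _fit_opls_core(X, y, n_orth=1)
        cosine = abs(model.w_orth[0][1]) / np.linalg.norm(model.w_orth[0])
        assert cosine > 0.99
        # and removing it leaves the predictive scores proportional to y
        corr = np.corrcoef(model.t_pred, y)[0, 1]
        assert abs(corr) > 0.999

    def test_orthogonal_scores_uncorrelated_with_labels(self):
        X, y = _two_class_data(seed=3, ortho_sd=4.0)
        model = _fit_opls_core(X, y, n_orth=2)
        yc = y - y.mean()
        for t_o in model.t_orth:
            assert abs(t_o @ yc) / (np.linalg.norm(t_o) * np.linalg.norm(yc)) < 1e-8

    def test_r2y_in_unit_interval_and_single_class_rejected(self):
        X, y = _two_class_data(seed=4)
        model = fit_opls_da(X, y, n_orth=1, cv_folds=5)
        assert 0.0 <= model.r2y <= 1.0
        with pytest.raises(ValueError):
            fit_opls_da(X, np.ones_like(y))


class TestQ2:
    def test_separable_data_gives_high_q2(self):
        X, y, groups = simulate_paired_features(10, 6, {0: 2.0, 1: 2.0},
                                                within_sd=0.3, seed=5)
        q2 = q2_cv(X.to_numpy(), y, n_orth=0, folds=10, groups=groups)
        assert q2 > 0.5

    def test_permuted_labels_give_no_predictive_power(self):
        rng = np.random.default_rng(6)
        q2s = []
        for seed in range(40):
            X, y, groups = simulate_paired_features(10, 6, None, seed=seed)
            yp = y * rng.choice([-1.0, 1.0], size=len(y))
            q2s.append(q2_cv(X.to_numpy(), yp, folds=5, groups=groups))
        assert np.mean(q2s) < 0.05

    def test_duplicating_dataset_raises_q2(self):
        X, y, groups = simulate_paired_features(8, 5, {0: 1.2},
                                                within_sd=0.8, seed=7)
        Xv = X.to_numpy()
        q2_single = q2_cv(Xv, y, folds=4, groups=groups)
        X2 = np.vstack([Xv, Xv])
        y2 = np.concatenate([y, y])
        g2 = np.concatenate([groups, groups + 100])
        q2_double = q2_cv(X2, y2, folds=4, groups=g2)
        assert q2_double > q2_single


class TestPermutation:
    def test_minimum_attainable_p(self):
        X, y = _two_class_data(seed=8, sep=6.0)
        groups = np.tile(np.arange(10), 2)
        _, p = permutation_test(X, y, groups, statistic="R2Y", n_perm=199, seed=0)
        assert p >= 1.0 / 200
        # strongly separated data should sit at or near the floor
        assert p < 0.05

    def test_observed_equal_to_all_permuted_gives_one(self):
        # both samples of each pair share one row: every within-pair label
        # swap leaves the (degenerate, zero) statistic unchanged -> p = 1
        rng = np.random.default_rng(13)
        pair_rows = rng.normal(size=(4, 3))
        X = np.repeat(pair_rows, 2, axis=0)
        y = np.array([1.0, -1.0] * 4)
        groups = np.repeat(np.arange(4), 2)
        _, p = permutation_test(X, y, groups, statistic="R2Y", n_perm=99, seed=0)
        assert p == 1.0

    def test_too_few_permutations_rejected(self):
        X, y = _two_class_data()
        with pytest.raises(ValueError):
            permutation_test(X, y, n_perm=5)


class TestRoc:
    def test_hand_counted_concordance(self):
        scores = np.array([0.9, 0.4, 0.5, 0.1])
        labels = np.array([1.0, 1.0, -1.0, -1.0])
        res = roc_from_scores(scores, labels, n_boot=100, seed=0)
        assert res.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        scores = np.array([2.0, 1.0, -1.0, -2.0])
        labels = np.array([1.0, 1.0, -1.0, -1.0])
        res = roc_from_scores(scores, labels, n_boot=100, seed=0)
        assert res.auc == 1.0
        assert res.accuracy == 1.0

    def test_label_flip_maps_auc(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=30)
        labels = np.where(rng.random(30) < 0.5, 1.0, -1.0)
        a = roc_from_scores(scores, labels, n_boot=50, seed=0).auc
        b = roc_from_scores(scores, -labels, n_boot=50, seed=0).auc
        assert a == pytest.approx(1.0 - b)

    def test_concordance_equals_trapezoidal_roc_area(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            n = rng.integers(8, 50)
            scores = np.round(rng.normal(size=n), 1)
            labels = np.where(rng.random(n) < 0.5, 1.0, -1.0)
            if len(set(labels)) < 2:
                continue
            res = roc_from_scores(scores, labels, n_boot=10, seed=0)
            if res.degenerate:
                continue
            area = sk_auc(res.fpr, res.tpr)
            assert res.auc == pytest.approx(area, abs=1e-12)

    def test_curve_monotone_and_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=40) + np.repeat([0.8, 0.0], 20)
        labels = np.repeat([1.0, -1.0], 20)
        res = roc_from_scores(scores, labels, n_boot=500, seed=1)
        assert (np.diff(res.fpr) >= 0).all()
        assert (np.diff(res.tpr) >= 0).all()
        lo, hi = res.ci95
        assert lo <= hi

    def test_constant_scores_degenerate(self):
        res = roc_from_scores(np.zeros(6), np.array([1.0, 1, 1, -1, -1, -1]),
                              n_boot=10, seed=0)
        assert res.degenerate
        assert res.auc == 0.5


def test_cv_scores_never_use_own_subject():
    # a subject's pair carries a unique giveaway feature; grouped CV must not see it
    rng = np.random.default_rng(12)
    n_subj = 8
    y = np.tile([1.0, -1.0], n_subj)
    groups = np.repeat(np.arange(n_subj), 2)
    X = rng.normal(size=(2 * n_subj, n_subj))
    for s in range(n_subj):  # feature s is informative only within subject s
        X[groups == s, s] = y[groups == s] * 10.0
    scores = cross_validated_scores(X, y, groups, folds=n_subj, seed=0)
    assert auc_concordance(scores, y) < 0.9
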