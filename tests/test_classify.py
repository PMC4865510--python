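"""FLDA, time-ordered splits, stacking fusion, exact Wilcoxon."""

from itertools import product

import numpy as np
import pytest

from drivefatigue.classify import (FisherLDA, StackedFLDA, evaluate_modality,
                                   fuse_classifiers, make_splits,
                                   wilcoxon_signed_rank_exact)


def circular_gap(i, j, n):
    d = abs(int(i) - int(j))
    return min(d, n - d)


class TestSplits:
    def test_default_bookkeeping(self):
        splits = make_splits()
        assert splits.n_reps == 30
        for tr, te in zip(splits.train, splits.test):
            assert len(tr) == 120 and len(te) == 48
            assert len(set(tr) & set(te)) == 0

    def test_first_repetition_blocks(self):
        splits = make_splits()
        assert np.array_equal(splits.train[0], np.arange(120))
        assert np.array_equal(splits.test[0], np.arange(126, 174))

    def test_one_minute_buffer_everywhere(self):
        splits = make_splits()
        n = 180
        for tr, te in zip(splits.train, splits.test):
            # every train trial is at least 6 slots (1 min) from every test trial
            gaps = [circular_gap(i, j, n) for i in tr for j in te]
            assert min(gaps) >= 6

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            make_splits(n_trials=100, train_frac=0.333)  # non-integral block
        with pytest.raises(ValueError):
            make_splits(n_trials=20, buffer_trials=15)


class TestFisherLDA:
    def test_one_dimensional_boundary_at_midpoint(self, rng):
        X = np.r_[rng.normal(0, 1, 500), rng.normal(3, 1, 500)]
        y = np.r_[np.zeros(500, int), np.ones(500, int)]
        model = FisherLDA().fit(X, y)
        boundary = -model.intercept_ / model.coef_[0]
        assert model.coef_[0] > 0
        assert boundary == pytest.approx(1.5, abs=0.2)

    def test_irrelevant_feature_downweighted(self, rng):
        n = 1000
        X = np.column_stack([np.r_[rng.normal(0, 1, n), rng.normal(3, 1, n)],
                             rng.normal(0, 1, 2 * n)])
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        model = FisherLDA().fit(X, y)
        assert abs(model.coef_[1]) / abs(model.coef_[0]) < 0.1

    def test_label_swap_flips_weights(self, rng):
        X = rng.standard_normal((200, 3))
        y = (rng.random(200) > 0.5).astype(int)
        a = FisherLDA().fit(X, y)
        b = FisherLDA().fit(X, 1 - y)
        assert np.allclose(a.coef_, -b.coef_, rtol=1e-9)

    def test_matches_reference_lda_direction(self, rng):
        """Weight vector is parallel to scikit-learn's LSQR LDA solution."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = rng.standard_normal((400, 4)) + 0.5
        y = (rng.random(400) > 0.5).astype(int)
        X[y == 1] += [1.0, 0.5, 0.0, -0.5]
        ours = FisherLDA(shrinkage=0.0).fit(X, y)
        ref = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        cos = ours.coef_ @ ref.coef_[0] / (
            np.linalg.norm(ours.coef_) * np.linalg.norm(ref.coef_[0]))
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_weight_closed_form_identity(self, rng):
        X = rng.standard_normal((300, 3))
        y = (rng.random(300) > 0.5).astype(int)
        X[y == 1] += 1.0
        m = FisherLDA(shrinkage=1e-3).fit(X, y)
        lam = 1e-3 * np.trace(m.covariance_) / 3
        w = np.linalg.solve(m.covariance_ + lam * np.eye(3), m.means_[1] - m.means_[0])
        assert np.allclose(m.coef_, w, rtol=1e-9)

    def test_predicts_class_means(self, rng):
        X = np.r_[rng.normal(0, 0.1, (50, 2)), rng.normal(5, 0.1, (50, 2))]
        y = np.r_[np.zeros(50, int), np.ones(50, int)]
        m = FisherLDA().fit(X, y)
        assert m.predict(m.means_[:1])[0] == 0
        assert m.predict(m.means_[1:])[0] == 1

    def test_boundary_tie_goes_to_class_zero(self):
        X = np.array([[0.0], [1.0], [0.1], [0.9]])
        y = np.array([0, 1, 0, 1])
        m = FisherLDA().fit(X, y)
        midpoint = np.array([[0.5]])
        assert m.decision_function(midpoint)[0] == pytest.approx(0.0, abs=1e-12)
        assert m.predict(midpoint)[0] == 0

    def test_single_class_and_dim_mismatch_errors(self, rng):
        with pytest.raises(ValueError):
            FisherLDA().fit(rng.standard_normal((10, 2)), np.zeros(10))
        m = FisherLDA().fit(rng.standard_normal((10, 2)), np.r_[np.zeros(5), np.ones(5)])
        with pytest.raises(ValueError):
            m.predict(rng.standard_normal((3, 5)))

    def test_sklearn_get_set_params(self):
        m = FisherLDA(shrinkage=0.5)
        assert m.get_params() == {"shrinkage": 0.5}
        m.set_params(shrinkage=0.1)
        assert m.shrinkage == 0.1


class TestEvaluateModality:
    def test_chance_level_for_identical_distributions(self):
        accs = []
        splits = make_splits()
        for seed in range(5):
            r = np.random.default_rng(seed)
            accs.append(evaluate_modality(r.standard_normal((180, 2)),
                                          r.standard_normal((180, 2)), splits).mean())
        assert 0.4 < np.mean(accs) < 0.6

    def test_separable_features_are_perfect(self, rng):
        splits = make_splits()
        acc = evaluate_modality(rng.normal(0, 0.1, (180, 1)),
                                rng.normal(10, 0.1, (180, 1)), splits)
        assert np.all(acc == 1.0)

    def test_dprime_three_accuracy(self):
        # d' = 3 => Bayes accuracy ~ Phi(1.5) ~ 0.933
        accs = [evaluate_modality(np.random.default_rng(s).normal(0, 1, (180, 1)),
                                  np.random.default_rng(s + 100).normal(3, 1, (180, 1)),
                                  make_splits()).mean() for s in range(3)]
        assert np.mean(accs) >= 0.90


class TestFusion:
    def test_informative_plus_noise_not_degraded(self, rng):
        splits = make_splits()
        informative_w = rng.normal(0, 1, (180, 1))
        informative_s = rng.normal(3, 1, (180, 1))
        noise_w, noise_s = rng.standard_normal((180, 1)), rng.standard_normal((180, 1))
        alone = evaluate_modality(informative_w, informative_s, splits).mean()
        fused = fuse_classifiers([informative_w, noise_w], [informative_s, noise_s],
                                 splits).mean()
        assert fused >= alone - 0.02

    def test_redundant_copies_match_single(self, rng):
        splits = make_splits()
        w = rng.normal(0, 1, (180, 1))
        s = rng.normal(1.5, 1, (180, 1))
        alone = evaluate_modality(w, s, splits).mean()
        fused = fuse_classifiers([w, w, w], [s, s, s], splits).mean()
        assert fused == pytest.approx(alone, abs=0.02)

    def test_three_weak_modalities_fuse_above_best_single(self):
        wins = 0
        for seed in range(6):
            r = np.random.default_rng(seed)
            d = 0.77  # single-modality Bayes accuracy ~ 0.65
            W = [r.normal(0, 1, (180, 1)) for _ in range(3)]
            S = [r.normal(d, 1, (180, 1)) for _ in range(3)]
            splits = make_splits()
            singles = [evaluate_modality(w, s, splits).mean() for w, s in zip(W, S)]
            fused = fuse_classifiers(W, S, splits).mean()
            wins += int(fused > max(singles))
        assert wins >= 4

    def test_single_modality_rejected(self, rng):
        with pytest.raises(ValueError):
            fuse_classifiers([rng.standard_normal((180, 1))],
                             [rng.standard_normal((180, 1))], make_splits())

    def test_stacked_estimator_interface(self, rng):
        X = np.column_stack([rng.standard_normal(200), rng.standard_normal(200)])
        y = (rng.random(200) > 0.5).astype(int)
        X[y == 1] += 2.0
        m = StackedFLDA(feature_groups=[[0], [1]]).fit(X, y)
        assert set(m.get_params()) == {"feature_groups", "n_folds", "shrinkage"}
        assert (m.predict(X) == y).mean() > 0.8


class TestWilcoxonExact:
    def test_all_positive_eleven_pairs(self):
        w, p = wilcoxon_signed_rank_exact(np.arange(1.0, 12.0), np.zeros(11))
        assert w == 66.0
        assert p == pytest.approx(2 / 2 ** 11)

    def test_symmetric_differences_center(self):
        a = np.array([1.0, -1.0, 2.0, -2.0])
        _, p = wilcoxon_signed_rank_exact(a, np.zeros(4))
        assert p == 1.0

    def test_matches_brute_force_enumeration(self, rng):
        from scipy.stats import rankdata

        for _ in range(5):
            d = rng.normal(size=5)
            ranks = rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()
            dist = [sum(r for r, s in zip(ranks, signs) if s)
                    for signs in product([0, 1], repeat=5)]
            dist = np.asarray(dist, float)
            p_expect = min(1.0, 2 * min((dist <= w_obs).mean(), (dist >= w_obs).mean()))
            w, p = wilcoxon_signed_rank_exact(d, np.zeros(5))
            assert w == w_obs
            assert p == pytest.approx(p_expect, abs=1e-12)

    def test_matches_scipy_exact(self, rng):
        from scipy.stats import wilcoxon

        for n in (4, 6, 8, 10):
            a, b = rng.normal(size=n), rng.normal(size=n)
            _, p = wilcoxon_signed_rank_exact(a, b)
            assert p == pytest.approx(wilcoxon(a, b, method="exact").pvalue, abs=1e-12)

    def test_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank_exact(np.ones(5), np.ones(5))
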