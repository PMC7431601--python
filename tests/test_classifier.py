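"""Windowed-means features, shrinkage LDA, margin CV, chance thresholds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

import neurotrace as nt
from neurotrace.classifier import (
    CVConfig,
    FeatureConfig,
    RelevanceModel,
    chance_threshold,
    cross_validate,
    extract_windowed_means,
    fit_shrinkage_lda,
    predict_relevance,
)
from neurotrace.exceptions import (
    ConfigurationError,
    DegenerateInputError,
    ModelMismatchError,
    ParameterError,
)
from neurotrace.prep import EpochSet
from conftest import toy_gaussians


def _epochs(data, fs=500.0, window=(-0.2, 0.8), labels=None):
    labels = labels if labels is not None else np.zeros(data.shape[0], dtype=int)
    return EpochSet(data, window, labels, fs)


class TestWindowedMeans:
    def test_constant_signal_gives_constant_features(self):
        ep = _epochs(np.ones((3, 2, 500)))
        X = extract_windowed_means(ep)
        assert X.shape == (3, 16)
        np.testing.assert_allclose(X, 1.0)

    def test_default_layout_gives_256_features_for_32_channels(self):
        ep = _epochs(np.zeros((2, 32, 500)))
        assert extract_windowed_means(ep).shape == (2, 8 * 32)

    def test_features_match_direct_sample_means(self):
        # brute-force oracle: slice the raw samples and average them
        rng = np.random.default_rng(0)
        ep = _epochs(rng.normal(size=(10, 4, 500)))
        cfg = FeatureConfig()
        X = extract_windowed_means(ep, cfg)
        fs = ep.fs_hz
        onset = int(round(0.2 * fs))
        for w in range(cfg.n_windows):
            a = onset + int(round((0.150 + w * 0.050) * fs))
            b = a + int(round(0.050 * fs))
            np.testing.assert_allclose(
                X[:, w * 4 : (w + 1) * 4], ep.epochs[:, :, a:b].mean(axis=2), atol=1e-9
            )

    def test_window_major_feature_order(self):
        # channel c constant at value c, so every window-w block is (0,1,..)
        data = np.tile(np.arange(3.0)[None, :, None], (2, 1, 500))
        X = extract_windowed_means(_epochs(data))
        np.testing.assert_allclose(X[0], np.tile(np.arange(3.0), 8))

    def test_trial_and_channel_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        ep = _epochs(rng.normal(size=(8, 5, 500)))
        X = extract_windowed_means(ep)
        pt = rng.permutation(8)
        np.testing.assert_allclose(
            extract_windowed_means(_epochs(ep.epochs[pt])), X[pt]
        )
        pc = rng.permutation(5)
        Xc = extract_windowed_means(_epochs(ep.epochs[:, pc, :]))
        for w in range(8):
            np.testing.assert_allclose(Xc[:, w * 5 : (w + 1) * 5], X[:, w * 5 : (w + 1) * 5][:, pc])

    def test_epoch_too_short_raises(self):
        ep = _epochs(np.zeros((2, 2, 100)), window=(0.0, 0.2))
        with pytest.raises(ConfigurationError):
            extract_windowed_means(ep)


class TestShrinkageLDA:
    def test_gamma_zero_matches_closed_form_direction(self):
        # analytic oracle: w = Sigma^-1 (mu1 - mu0) from the sample moments
        X, y = toy_gaussians(n_per_class=500, d=2, delta=2.0, seed=3)
        res = fit_shrinkage_lda(X, y, shrinkage=0.0)
        mu0, mu1 = X[y == 0].mean(0), X[y == 1].mean(0)
        Xc = np.vstack([X[y == 0] - mu0, X[y == 1] - mu1])
        S = Xc.T @ Xc / (len(X) - 2)
        w_ref = np.linalg.solve(S, mu1 - mu0)
        cos = w_ref @ res.weights / (np.linalg.norm(w_ref) * np.linalg.norm(res.weights))
        assert abs(cos - 1.0) < 1e-6

    def test_gamma_one_reduces_to_nearest_class_mean(self):
        X, y = toy_gaussians(n_per_class=100, d=3, delta=2.0, seed=4)
        res = fit_shrinkage_lda(X, y, shrinkage=1.0)
        mu0, mu1 = X[y == 0].mean(0), X[y == 1].mean(0)
        # identity covariance: weights parallel to the mean difference
        diff = mu1 - mu0
        cos = diff @ res.weights / (np.linalg.norm(diff) * np.linalg.norm(res.weights))
        assert abs(cos - 1.0) < 1e-9
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(50, 3), scale=3.0)
        nearest = np.where(
            np.linalg.norm(pts - mu1, axis=1) < np.linalg.norm(pts - mu0, axis=1), 1, 0
        )
        np.testing.assert_array_equal(res.predict(pts), nearest)

    def test_matches_sklearn_shrinkage_lda_direction(self):
        # independent implementation cross-check at a fixed shrinkage
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X, y = toy_gaussians(n_per_class=150, d=6, delta=1.5, seed=6)
        gamma = 0.3
        res = fit_shrinkage_lda(X, y, shrinkage=gamma)
        sk = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=gamma).fit(X, y)
        w_sk = sk.coef_.ravel()
        cos = w_sk @ res.weights / (np.linalg.norm(w_sk) * np.linalg.norm(res.weights))
        assert abs(cos - 1.0) < 1e-8

    def test_single_class_raises(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(DegenerateInputError):
            RelevanceModel(X, np.zeros(10, dtype=int))

    def test_zero_variance_feature_survives_with_shrinkage(self):
        X, y = toy_gaussians(n_per_class=50, d=3, seed=7)
        X = np.c_[X, np.ones(len(X))]
        res = fit_shrinkage_lda(X, y, shrinkage=0.5)
        assert np.all(np.isfinite(res.weights))

    def test_decision_invariant_to_global_offset(self):
        X, y = toy_gaussians(n_per_class=80, d=4, seed=8)
        res = fit_shrinkage_lda(X, y, 0.2)
        res_shift = fit_shrinkage_lda(X + 11.5, y, 0.2)
        pts = np.random.default_rng(9).normal(size=(30, 4))
        np.testing.assert_array_equal(res.predict(pts), res_shift.predict(pts + 11.5))


class TestRelevanceScores:
    def test_class_prototypes_score_on_their_sides(self):
        X, y = toy_gaussians(n_per_class=200, d=2, delta=4.0, seed=10)
        res = fit_shrinkage_lda(X, y)
        mu0, mu1 = X[y == 0].mean(0), X[y == 1].mean(0)
        s0 = predict_relevance(res, mu0[None, :])[0]
        s1 = predict_relevance(res, mu1[None, :])[0]
        assert s0.value < 1.5 and not s0.relevant
        assert s1.value >= 1.5 and s1.relevant

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=2))
    def test_scores_always_in_unit_band(self, point):
        X, y = toy_gaussians(n_per_class=50, d=2, seed=11)
        res = fit_shrinkage_lda(X, y)
        s = predict_relevance(res, np.array(point)[None, :])[0]
        assert 1.0 <= s.value <= 2.0

    def test_dimension_mismatch_raises(self):
        X, y = toy_gaussians(n_per_class=30, d=4, seed=12)
        res = fit_shrinkage_lda(X, y)
        with pytest.raises(ModelMismatchError):
            res.predict(np.zeros((2, 5)))

    def test_serialization_round_trip(self, tmp_path):
        X, y = toy_gaussians(n_per_class=40, d=3, seed=13)
        res = fit_shrinkage_lda(X, y)
        res.to_json(tmp_path / "model.json")
        back = nt.RelevanceResults.from_json(tmp_path / "model.json")
        pts = np.random.default_rng(14).normal(size=(20, 3))
        np.testing.assert_allclose(back.relevance(pts), res.relevance(pts), atol=1e-12)


class TestCrossValidation:
    def test_separable_data_scores_perfectly(self):
        X, y = toy_gaussians(n_per_class=100, d=2, delta=30.0, seed=15)
        res = cross_validate(X, y)
        assert res.mean_accuracy == 1.0

    def test_default_config_is_five_folds_margin_five(self):
        cfg = CVConfig()
        assert cfg.n_folds == 5 and cfg.margin_trials == 5

    def test_margin_trials_excluded_from_training(self, monkeypatch):
        # spy on the training sets: the trials flanking each contiguous test
        # block must never appear in that fold's training data
        from neurotrace import classifier as clf

        recorded = []
        orig = clf.RelevanceModel

        class Spy(orig):
            def __init__(self, X, y, shrinkage="auto"):
                recorded.append(np.sort(X[:, 0]).astype(int))
                super().__init__(X, y, shrinkage)

        monkeypatch.setattr(clf, "RelevanceModel", Spy)
        n, m = 50, 3
        X = np.arange(n, dtype=float)[:, None]
        y = np.arange(n) % 2
        clf.cross_validate(X, y, CVConfig(n_folds=5, margin_trials=m), shrinkage=1.0)
        bounds = [0, 10, 20, 30, 40, 50]
        for i, (a, b) in enumerate(zip(bounds, bounds[1:])):
            expected = np.r_[0 : max(a - m, 0), min(b + m, n) : n]
            np.testing.assert_array_equal(recorded[i], expected)

    def test_no_signal_accuracy_never_clears_chance_threshold(self):
        # with identical class means the decoder must not look significant:
        # accuracy stays at or below the majority proportion (plus binomial
        # slack) and under the exact-binomial chance threshold, for any gamma
        rng = np.random.default_rng(16)
        n, d = 500, 64
        y = np.zeros(n, dtype=int)
        y[rng.choice(n, 75, replace=False)] = 1
        X = rng.normal(size=(n, d))
        maj = max(1 - y.mean(), y.mean())
        thr = chance_threshold(n, maj, alpha=0.05)
        for gamma in ("auto", 0.0, 1.0):
            res = cross_validate(X, y, shrinkage=gamma)
            assert res.mean_accuracy < thr
            assert res.mean_accuracy <= maj + 2.576 * np.sqrt(maj * (1 - maj) / n)

    def test_too_few_trials_raises(self):
        with pytest.raises(ParameterError):
            cross_validate(np.zeros((3, 2)), np.array([0, 1, 0]), CVConfig(n_folds=5))


class TestChanceThreshold:
    def test_balanced_hundred_trials_threshold_is_059(self):
        # exact binomial oracle: smallest k with P(X >= k) <= 0.05 is 59
        assert chance_threshold(100, 0.5, 0.05) == pytest.approx(0.59)
        assert binom.sf(58, 100, 0.5) <= 0.05 < binom.sf(57, 100, 0.5)

    def test_alpha_one_degenerates_to_zero(self):
        assert chance_threshold(100, 0.5, 1.0) == 0.0

    def test_monotone_in_n_and_proportion(self):
        for p in (0.5, 0.7, 0.857):
            ts = [chance_threshold(n, p) for n in (50, 100, 200, 400, 800)]
            assert all(a >= b for a, b in zip(ts, ts[1:]))
        for n in (50, 200, 800):
            ts = [chance_threshold(n, p) for p in (0.5, 0.6, 0.7, 0.8, 0.9)]
            assert all(a <= b for a, b in zip(ts, ts[1:]))

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ParameterError):
            chance_threshold(100, 0.5, 0.0)
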