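"""Histogram frames, softmax regression with MSGD, and the integer
weight-scaling map to the spiking classifier."""

import numpy as np
import pytest
from scipy.special import softmax as scipy_softmax

from evsnn.aer import EventStream
from evsnn.training import (SoftmaxClassifier, TrainConfig, build_histogram,
                            nll_loss, predict, scale_weights,
                            softmax_forward, softmax_gradient, train_msgd)


def flatten_stream(indices, ts=None, h=16):
    ts = ts if ts is not None else list(range(len(indices)))
    data = np.array([[t, j, 0, 1, -1] for t, j in zip(ts, indices)],
                    dtype=np.int64)
    return EventStream(data, h, 1, max(ts, default=0) + 1)


class TestHistogram:
    def test_normalization_by_max(self):
        v = build_histogram(flatten_stream([0, 0, 1]), h=4)
        assert v.tolist() == [1.0, 0.5, 0.0, 0.0]

    def test_empty_record_gives_zero_vector(self):
        v = build_histogram(flatten_stream([]), h=4)
        assert np.array_equal(v, np.zeros(4))

    def test_random_multiset_matches_brute_force(self, rng):
        idx = rng.integers(0, 32, 500).tolist()
        v = build_histogram(flatten_stream(idx, h=32), h=32)
        counts = np.zeros(32)
        for j in idx:
            counts[j] += 1
        assert np.allclose(v, counts / counts.max())

    def test_window_restricts_counts(self):
        s = flatten_stream([0, 1, 2], ts=[0, 10, 20])
        v = build_histogram(s, h=4, window=(5, 15))
        assert v.tolist() == [0.0, 1.0, 0.0, 0.0]

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ValueError):
            build_histogram(flatten_stream([7]), h=4)

    def test_determinism(self, rng):
        idx = rng.integers(0, 16, 100).tolist()
        a = build_histogram(flatten_stream(idx), h=16)
        b = build_histogram(flatten_stream(idx), h=16)
        assert np.array_equal(a, b)


class TestSoftmax:
    def test_zero_weights_give_uniform(self):
        probs = softmax_forward(np.zeros((4, 8)), np.ones(8))
        assert np.allclose(probs, 0.25)

    def test_probabilities_normalize(self, rng):
        W = rng.normal(size=(5, 12))
        X = rng.uniform(size=(20, 12))
        probs = softmax_forward(W, X)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_independent_implementation(self, rng):
        W = rng.normal(size=(6, 9)) * 10
        x = rng.uniform(size=9)
        assert np.allclose(softmax_forward(W, x), scipy_softmax(W @ x),
                           atol=1e-12)

    def test_nll_uniform_is_log_k(self):
        X = np.ones((3, 8))
        labels = np.array([0, 1, 2])
        assert nll_loss(np.zeros((4, 8)), X, labels) == pytest.approx(
            np.log(4))

    def test_nll_confident_correct_approaches_zero(self):
        W = np.zeros((2, 2))
        W[0, 0] = W[1, 1] = 50.0
        X = np.eye(2)
        assert nll_loss(W, X, np.array([0, 1])) < 1e-10

    def test_nll_matches_term_by_term_sum(self, rng):
        W = rng.normal(size=(3, 7))
        X = rng.uniform(size=(11, 7))
        labels = rng.integers(0, 3, 11)
        total = 0.0
        for xi, li in zip(X, labels):
            logits = W @ xi
            probs = np.exp(logits - logits.max())
            probs /= probs.sum()
            total -= np.log(probs[li])
        assert nll_loss(W, X, labels) == pytest.approx(total / 11)


class TestGradient:
    def test_matches_central_differences(self, rng):
        W = rng.normal(size=(3, 6)) * 0.5
        X = rng.uniform(size=(8, 6))
        labels = rng.integers(0, 3, 8)
        grad = softmax_gradient(W, X, labels)
        eps = 1e-6
        num = np.zeros_like(W)
        for i in range(W.shape[0]):
            for j in range(W.shape[1]):
                Wp, Wm = W.copy(), W.copy()
                Wp[i, j] += eps
                Wm[i, j] -= eps
                num[i, j] = (nll_loss(Wp, X, labels)
                             - nll_loss(Wm, X, labels)) / (2 * eps)
        assert np.abs(grad - num).max() < 1e-6


class TestMSGD:
    def test_zero_learning_rate_is_a_no_op(self, rng):
        X = rng.uniform(size=(10, 5))
        y = rng.integers(0, 2, 10)
        y[:2] = [0, 1]
        W, _ = train_msgd(X, y, 2, TrainConfig(eta=0.0, epochs=5,
                                               batch_size=5, seed=0))
        assert np.array_equal(W, np.zeros((2, 5)))

    def test_separable_toy_set_reaches_full_accuracy(self, rng):
        # 20 samples separable by a hyperplane through the origin (the
        # model has no bias): classes occupy different feature directions
        X = np.abs(rng.normal(0.1, 0.05, (20, 4)))
        X[:10, :2] += 0.8   # class 0 energy on features 0-1
        X[10:, 2:] += 0.8   # class 1 energy on features 2-3
        y = np.array([0] * 10 + [1] * 10)
        W, _ = train_msgd(X, y, 2, TrainConfig(eta=0.1, epochs=200,
                                               batch_size=10, seed=1))
        assert np.mean(predict(W, X) == y) == 1.0

    def test_seeded_shuffling_is_reproducible(self, rng):
        X = rng.uniform(size=(20, 6))
        y = rng.integers(0, 3, 20)
        y[:3] = [0, 1, 2]
        cfg = TrainConfig(eta=0.1, epochs=20, batch_size=7, seed=5)
        W1, _ = train_msgd(X, y, 3, cfg)
        W2, _ = train_msgd(X, y, 3, cfg)
        assert np.array_equal(W1, W2)

    def test_empty_class_rejected(self):
        X = np.ones((4, 3))
        y = np.array([0, 0, 1, 1])
        with pytest.raises(ValueError, match="class 2"):
            train_msgd(X, y, 3, TrainConfig(epochs=1, batch_size=2))


class TestPredict:
    def test_basis_vector_selects_matching_row(self):
        W = np.eye(4)
        assert predict(W, np.eye(4)[2]) == 2

    def test_tie_goes_to_lowest_index(self):
        assert predict(np.zeros((3, 5)), np.ones(5)) == 0

    def test_agrees_with_softmax_argmax(self, rng):
        W = rng.normal(size=(5, 9))
        X = rng.uniform(size=(30, 9))
        assert np.array_equal(predict(W, X),
                              np.argmax(softmax_forward(W, X), axis=1))

    def test_scale_invariance(self, rng):
        W = rng.normal(size=(4, 7))
        X = rng.uniform(size=(25, 7))
        assert np.array_equal(predict(W, X), predict(3.7 * W, X))


class TestScaleWeights:
    def test_half_maps_to_five_million(self):
        w_int, err = scale_weights(np.array([[0.5]]), 10_000_000)
        assert w_int[0, 0] == 5_000_000
        assert err <= 0.5

    def test_zero_stays_zero(self):
        w_int, _ = scale_weights(np.zeros((2, 3)))
        assert np.all(w_int == 0)

    def test_argmax_preserved_when_logit_gap_dominates_rounding(self, rng):
        k = 10_000_000
        h = 50
        for _ in range(20):
            W = rng.normal(size=(4, h))
            counts = rng.integers(0, 20, h).astype(float)
            w_int, _ = scale_weights(W, k)
            logits = W @ counts
            order = np.sort(logits)
            if order[-1] - order[-2] > h * 0.5 / k * counts.max():
                assert np.argmax(w_int @ counts) == np.argmax(logits)

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            scale_weights(np.ones((1, 1)), 0)

    def test_overflow_detected(self):
        with pytest.raises(OverflowError):
            scale_weights(np.array([[1e12]]), 10_000_000)


class TestModelObjects:
    def test_fit_predict_summary(self, rng):
        X = np.abs(rng.normal(0.1, 0.05, (30, 6)))
        X[:15, :3] += 0.8
        X[15:, 3:] += 0.8
        y = np.array([0] * 15 + [1] * 15)
        fit = SoftmaxClassifier(X, y).fit(eta=0.1, epochs=100, batch_size=10,
                                          seed=2, loss_every=50)
        assert fit.accuracy() == 100.0
        assert len(fit.loss_history) == 2
        assert fit.loss_history[-1] <= fit.loss_history[0]
        w_int, th_fc, err = fit.scale_weights()
        assert th_fc == 10_000_000
        assert w_int.dtype == np.int64
        text = fit.summary()
        assert "Softmax" in text and "Epochs" in text

    def test_label_validation(self):
        with pytest.raises(ValueError):
            SoftmaxClassifier(np.ones((2, 3)), np.array([0, 5]), n_classes=2)
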