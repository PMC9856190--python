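"""CNN discriminators and KNN baseline: architecture arithmetic, training
contracts, determinism."""

import numpy as np
import pytest

from polraman import _nn
from polraman.models import CNN1DClassifier, CNN2DClassifier, KNNImageClassifier


def make_separable_images(n_per_class, size=8, seed=0):
    """All-red vs all-blue images: trivially separable."""
    rng = np.random.default_rng(seed)
    red = np.zeros((n_per_class, size, size, 3), dtype=np.float32)
    red[..., 0] = 1.0
    blue = np.zeros((n_per_class, size, size, 3), dtype=np.float32)
    blue[..., 2] = 1.0
    X = np.concatenate([red, blue]) + rng.normal(0, 0.02, (2 * n_per_class, size, size, 3)).astype(np.float32)
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return np.clip(X, 0, 1), y


class TestArchitecture:
    def test_2d_feature_map_arithmetic(self):
        """100x100 through two 2x2/2 pools -> 25x25 spatial features."""
        X, y = make_separable_images(4, size=100)
        clf = CNN2DClassifier(max_iters=1, eval_every=1, random_state=0)
        clf.fit(X, y, X_val=X, y_val=y)
        fc1 = [ly for ly in clf.net_.layers if isinstance(ly, _nn.Dense)][0]
        assert fc1.params["W"].shape == (32 * 25 * 25, 128)

    def test_1d_feature_length_arithmetic(self):
        """1780 channels through two stride-2 pools -> 445-length features."""
        rng = np.random.default_rng(0)
        X = rng.random((8, 1780)).astype(np.float32)
        y = np.array([0, 1] * 4)
        clf = CNN1DClassifier(max_iters=1, eval_every=1, random_state=0)
        clf.fit(X, y, X_val=X, y_val=y)
        fc1 = [ly for ly in clf.net_.layers if isinstance(ly, _nn.Dense)][0]
        assert fc1.params["W"].shape == (32 * 445, 128)

    def test_2d_parameter_count_closed_form(self):
        """Conv1 (3*3*3+1)*16, BN 2*16, Conv2 (3*3*16+1)*32, BN 2*32,
        FC1 (20000+1)*128, FC2 129."""
        X, y = make_separable_images(4, size=100)
        clf = CNN2DClassifier(max_iters=1, eval_every=1, random_state=0)
        clf.fit(X, y, X_val=X, y_val=y)
        expected = (27 + 1) * 16 + 32 + (144 + 1) * 32 + 64 + 20001 * 128 + 129
        assert clf.n_parameters() == expected == 2565441

    def test_probabilities_in_unit_interval(self):
        X, y = make_separable_images(4, size=8)
        clf = CNN2DClassifier(max_iters=5, eval_every=5, random_state=0).fit(
            X, y, X_val=X, y_val=y
        )
        p = clf.predict_proba(X)
        assert p.shape == (len(X), 2)
        assert np.all((p > 0) & (p < 1))
        np.testing.assert_allclose(p.sum(axis=1), 1.0)

    def test_input_validation(self):
        clf = CNN2DClassifier()
        with pytest.raises(ValueError, match="shape"):
            clf._check_X(np.zeros((2, 100, 100)))
        with pytest.raises(ValueError, match="divisible"):
            clf._check_X(np.zeros((2, 10, 10, 3)))
        with pytest.raises(ValueError, match="divisible"):
            CNN1DClassifier()._check_X(np.zeros((2, 1781)))


class TestTraining:
    def test_separable_classes_learned(self):
        X, y = make_separable_images(16, size=8)
        clf = CNN2DClassifier(
            lr=3e-3, batch_size=16, max_iters=300, eval_every=50,
            patience=10, random_state=0,
        ).fit(X, y, X_val=X, y_val=y)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_separable_spectra_learned(self):
        rng = np.random.default_rng(3)
        a = rng.normal(1.0, 0.05, (16, 64)).astype(np.float32)
        b = rng.normal(0.0, 0.05, (16, 64)).astype(np.float32)
        X = np.concatenate([a, b])
        y = np.array([0] * 16 + [1] * 16)
        clf = CNN1DClassifier(
            lr=3e-3, batch_size=16, max_iters=300, eval_every=50,
            patience=10, random_state=0,
        ).fit(X, y, X_val=X, y_val=y)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_same_seed_identical_history(self):
        X, y = make_separable_images(8, size=8)
        kw = dict(lr=1e-3, batch_size=8, max_iters=30, eval_every=10, random_state=5)
        h1 = CNN2DClassifier(**kw).fit(X, y, X_val=X, y_val=y).history_
        h2 = CNN2DClassifier(**kw).fit(X, y, X_val=X, y_val=y).history_
        assert h1.equals(h2)

    def test_best_checkpoint_no_worse_than_final(self):
        X, y = make_separable_images(8, size=8)
        clf = CNN2DClassifier(
            lr=1e-3, batch_size=8, max_iters=50, eval_every=10, random_state=2
        ).fit(X, y, X_val=X, y_val=y)
        assert clf.best_val_loss_ <= clf.history_.val_loss.iloc[-1] + clf.min_delta

    def test_two_classes_required(self):
        X, _ = make_separable_images(4, size=8)
        with pytest.raises(ValueError, match="2 classes"):
            CNN2DClassifier(max_iters=1).fit(X, np.zeros(len(X)))


class TestKNN:
    def test_k1_recalls_training_set(self, rng):
        X = rng.random((10, 6, 6, 3)).astype(np.float32)
        y = rng.integers(0, 2, 10)
        y[0], y[1] = 0, 1  # both classes present
        knn = KNNImageClassifier(n_neighbors=1).fit(X, y)
        np.testing.assert_array_equal(knn.predict(X), y)

    def test_agrees_with_bruteforce_oracle(self, rng):
        X = rng.random((20, 5, 5, 3)).astype(np.float32)
        y = rng.integers(0, 2, 20)
        Xq = rng.random((7, 5, 5, 3)).astype(np.float32)
        k = 5
        knn = KNNImageClassifier(n_neighbors=k).fit(X, y)
        pred = knn.predict(Xq)
        flat = X.reshape(20, -1).astype(np.float64)
        for i, q in enumerate(Xq.reshape(7, -1).astype(np.float64)):
            d = np.sqrt(((flat - q) ** 2).sum(axis=1))
            nearest = np.argsort(d, kind="stable")[:k]
            votes = np.bincount(y[nearest], minlength=2)
            assert pred[i] == int(np.argmax(votes))

    def test_k_larger_than_train_rejected(self, rng):
        X = rng.random((4, 3, 3, 3)).astype(np.float32)
        y = np.array([0, 1, 0, 1])
        with pytest.raises(ValueError, match="exceeds"):
            KNNImageClassifier(n_neighbors=5).fit(X, y)
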