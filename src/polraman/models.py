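"""Discrimination models: 2D-CNN on pseudo-color polarization images,
a 1D-CNN counterpart on conventional spectra, and a KNN baseline.

Both CNNs share the same depth and ordering:

    Conv -> BN -> LeakyReLU -> MaxPool -> Conv -> BN -> LeakyReLU ->
    MaxPool -> Flatten -> FC1 -> Dropout -> FC2 -> sigmoid

with binary cross-entropy loss and the Adam optimizer.  The scalar
output is the probability of label 1 (normal tissue); label 0 is
cancerous.  Training stops early when the validation loss fails to
improve by more than ``min_delta`` for ``patience`` consecutive
evaluations, and the best-validation weights are retained.

The estimators follow the scikit-learn protocol (``fit`` / ``predict`` /
``predict_proba``, ``get_params``, fitted attributes with a trailing
underscore) and compose with sklearn model selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier

from . import _nn

__all__ = ["CNN2DClassifier", "CNN1DClassifier", "KNNImageClassifier"]


class _BaseCNNClassifier(BaseEstimator, ClassifierMixin):
    """Shared training machinery of the two CNN discriminators."""

    def __init__(
        self,
        conv_channels=(16, 32),
        fc_width=128,
        dropout=0.5,
        leaky_slope=0.01,
        lr=5e-5,
        lr_min=None,
        batch_size=64,
        max_iters=2000,
        eval_every=100,
        patience=10,
        min_delta=1e-4,
        validation_fraction=0.3,
        random_state=0,
    ):
        self.conv_channels = conv_channels
        self.fc_width = fc_width
        self.dropout = dropout
        self.leaky_slope = leaky_slope
        self.lr = lr
        self.lr_min = lr_min
        self.batch_size = batch_size
        self.max_iters = max_iters
        self.eval_every = eval_every
        self.patience = patience
        self.min_delta = min_delta
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # subclass hooks -------------------------------------------------------
    def _check_X(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _build_net(self, X: np.ndarray, rng: np.random.Generator) -> _nn.Sequential:
        raise NotImplementedError

    # training -------------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        X = self._check_X(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(
                f"binary classifier requires exactly 2 classes, got {self.classes_}"
            )
        y01 = (y == self.classes_[1]).astype(np.float64)

        rng = np.random.default_rng(self.random_state)
        if X_val is None:
            idx = np.arange(len(y01))
            tr, va = train_test_split(
                idx,
                test_size=self.validation_fraction,
                stratify=y01,
                random_state=self.random_state,
            )
            X, X_val, y01, yv01 = X[tr], X[va], y01[tr], y01[va]
        else:
            X_val = self._check_X(X_val)
            yv01 = (np.asarray(y_val) == self.classes_[1]).astype(np.float64)

        self._rng = rng
        net = self._build_net(X, rng)
        opt = _nn.Adam(net, lr=self.lr)

        n = len(y01)
        batch = min(self.batch_size, n)

        order = rng.permutation(n)
        cursor = 0
        history = []
        best_loss = np.inf
        best_weights = net.get_weights()
        best_iter = 0
        stall = 0
        for it in range(1, self.max_iters + 1):
            if cursor + batch > n:
                order = rng.permutation(n)
                cursor = 0
            sel = order[cursor : cursor + batch]
            cursor += batch
            z = net.forward(X[sel], train=True)[:, 0]
            loss, dz = _nn.bce_with_logits(z, y01[sel])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss {loss} at iteration {it} "
                    f"(lr={self.lr}, batch={batch})"
                )
            net.backward(dz[:, None])
            if self.lr_min is not None:
                # cosine decay from lr to lr_min over the iteration budget
                frac = 0.5 * (1.0 + np.cos(np.pi * it / self.max_iters))
                opt.lr = self.lr_min + (self.lr - self.lr_min) * frac
            opt.step()

            if it % self.eval_every == 0 or it == self.max_iters:
                # training stream traced from the current minibatch (the
                # costly full-train evaluation adds nothing to early stopping)
                tr_loss = loss
                tr_acc = float(((z > 0) == (y01[sel] > 0.5)).mean())
                va_loss, va_acc = self._evaluate(net, X_val, yv01)
                history.append(
                    {
                        "iteration": it,
                        "train_loss": tr_loss,
                        "train_accuracy": tr_acc,
                        "val_loss": va_loss,
                        "val_accuracy": va_acc,
                    }
                )
                if best_loss - va_loss > self.min_delta:
                    best_loss = va_loss
                    best_weights = net.get_weights()
                    best_iter = it
                    stall = 0
                else:
                    stall += 1
                    if stall >= self.patience:
                        break

        net.set_weights(best_weights)
        self.net_ = net
        self.history_ = pd.DataFrame(history)
        self.n_iter_ = int(history[-1]["iteration"]) if history else 0
        self.best_iteration_ = best_iter
        self.best_val_loss_ = float(best_loss)
        return self

    def _evaluate(
        self, net: _nn.Sequential, X: np.ndarray, y01: np.ndarray, batch: int = 256
    ) -> tuple[float, float]:
        losses = []
        correct = 0
        for i in range(0, len(y01), batch):
            z = net.forward(X[i : i + batch], train=False)[:, 0]
            loss, _ = _nn.bce_with_logits(z, y01[i : i + batch])
            losses.append(loss * len(z))
            correct += int(((z > 0) == (y01[i : i + batch] > 0.5)).sum())
        return float(np.sum(losses) / len(y01)), correct / len(y01)

    # inference ------------------------------------------------------------
    def decision_function(self, X) -> np.ndarray:
        X = self._check_X(X)
        out = []
        for i in range(0, len(X), 256):
            out.append(self.net_.forward(X[i : i + 256], train=False)[:, 0])
        return np.concatenate(out)

    def predict_proba(self, X) -> np.ndarray:
        p1 = _nn.sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)
        return self.classes_[(p[:, 1] > 0.5).astype(int)]

    def n_parameters(self) -> int:
        return self.net_.n_parameters()


class CNN2DClassifier(_BaseCNNClassifier):
    """2D-CNN on (n, H, W, 3) pseudo-color images (default 100x100x3).

    Two 3x3 convolutions (16 then 32 channels) with BN/LeakyReLU and 2x2
    stride-2 max pooling reduce 100x100 to 25x25 spatial features before
    the fully connected head.
    """

    def __init__(self, kernel_size=3, **kwargs):
        super().__init__(**kwargs)
        self.kernel_size = kernel_size

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=_nn.F32)
        if X.ndim != 4 or X.shape[3] != 3:
            raise ValueError(f"expected images of shape (n, H, W, 3), got {X.shape}")
        if X.shape[1] % 4 or X.shape[2] % 4:
            raise ValueError("image height/width must be divisible by 4 (two 2x pools)")
        return np.ascontiguousarray(X)

    def _build_net(self, X: np.ndarray, rng: np.random.Generator) -> _nn.Sequential:
        c1, c2 = self.conv_channels
        _, h, w, _ = X.shape
        flat = c2 * (h // 4) * (w // 4)
        conv1 = _nn.Conv2d(3, c1, self.kernel_size, rng)
        conv1.needs_dx = False  # first layer: skip the input gradient
        return _nn.Sequential(
            [
                conv1,
                _nn.BatchNorm(c1),
                _nn.LeakyReLU(self.leaky_slope),
                _nn.MaxPool2d(),
                _nn.Conv2d(c1, c2, self.kernel_size, rng),
                _nn.BatchNorm(c2),
                _nn.LeakyReLU(self.leaky_slope),
                _nn.MaxPool2d(),
                _nn.Flatten(),
                _nn.Dense(flat, self.fc_width, rng),
                _nn.LeakyReLU(self.leaky_slope),
                _nn.Dropout(self.dropout, rng),
                _nn.Dense(self.fc_width, 1, rng),
            ]
        )


class CNN1DClassifier(_BaseCNNClassifier):
    """1D-CNN on (n, L) conventional spectra (default L = 1780).

    Same depth and layer ordering as the 2D model with 1-D convolutions
    (kernel length 7); two stride-2 pools reduce 1780 channels to
    445-length features.
    """

    def __init__(self, kernel_size=7, **kwargs):
        super().__init__(**kwargs)
        self.kernel_size = kernel_size

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=_nn.F32)
        if X.ndim != 2:
            raise ValueError(f"expected spectra of shape (n, L), got {X.shape}")
        if X.shape[1] % 4:
            raise ValueError("spectrum length must be divisible by 4 (two 2x pools)")
        return np.ascontiguousarray(X[:, :, None])

    def _build_net(self, X: np.ndarray, rng: np.random.Generator) -> _nn.Sequential:
        c1, c2 = self.conv_channels
        _, l, _ = X.shape
        flat = c2 * (l // 4)
        conv1 = _nn.Conv1d(1, c1, self.kernel_size, rng)
        conv1.needs_dx = False
        return _nn.Sequential(
            [
                conv1,
                _nn.BatchNorm(c1),
                _nn.LeakyReLU(self.leaky_slope),
                _nn.MaxPool1d(),
                _nn.Conv1d(c1, c2, self.kernel_size, rng),
                _nn.BatchNorm(c2),
                _nn.LeakyReLU(self.leaky_slope),
                _nn.MaxPool1d(),
                _nn.Flatten(),
                _nn.Dense(flat, self.fc_width, rng),
                _nn.LeakyReLU(self.leaky_slope),
                _nn.Dropout(self.dropout, rng),
                _nn.Dense(self.fc_width, 1, rng),
            ]
        )


class KNNImageClassifier(BaseEstimator, ClassifierMixin):
    """K-nearest-neighbour baseline: Euclidean distance on flattened
    pixel vectors, majority vote (distance ties resolved by training
    order, label ties by the smallest label, per sklearn's vote)."""

    def __init__(self, n_neighbors: int = 5):
        self.n_neighbors = n_neighbors

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32).reshape(len(X), -1)
        y = np.asarray(y)
        if self.n_neighbors > len(y):
            raise ValueError(
                f"n_neighbors={self.n_neighbors} exceeds {len(y)} training points"
            )
        self._knn = KNeighborsClassifier(
            n_neighbors=self.n_neighbors, algorithm="brute", metric="euclidean"
        )
        self._knn.fit(X, y)
        self.classes_ = self._knn.classes_
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=np.float32).reshape(len(X), -1)
        return self._knn.predict(X)

    def predict_proba(self, X):
        X = np.asarray(X, dtype=np.float32).reshape(len(X), -1)
        return self._knn.predict_proba(X)
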