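"""Minimal NumPy neural-network engine for the small CNN discriminators.

Implements exactly the layers the discrimination models need — same-padded
2-D/1-D convolution, batch normalization, leaky ReLU, 2x stride-2 max
pooling, dense, dropout — with hand-written backpropagation, a
binary-cross-entropy-with-logits loss and an Adam optimizer.  Everything
is float32, channels-last (NHWC), and driven by a single
``numpy.random.Generator``, so training runs are bit-reproducible on one
device.

Convolutions use shift-and-matmul: a same-padded k x k convolution is the
sum over the k^2 spatial offsets of a plain (N*H*W, C) @ (C, F) product.
With channels last, every shifted slice has contiguous W*C runs, so the
implied copies run at memcpy speed (an im2col patch matrix would gather
C-sized fragments instead, which dominates the runtime).
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """k x k same-padded convolution, stride 1, on (N, H, W, C) tensors."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        if k % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        std = np.sqrt(2.0 / (c_in * k * k))
        self.params = {
            "W": rng.normal(0.0, std, (k * k, c_in, c_out)).astype(F32),
            "b": np.zeros(c_out, dtype=F32),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self.needs_dx = True

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xp = xp if train else None
        self._shape = x.shape
        out = np.tile(self.params["b"], (n * h * w, 1))
        for di in range(self.k):
            for dj in range(self.k):
                sl = np.ascontiguousarray(xp[:, di : di + h, dj : dj + w, :])
                out += sl.reshape(n * h * w, c) @ self.params["W"][di * self.k + dj]
        return out.reshape(n, h, w, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        p = self.k // 2
        dflat = dout.reshape(n * h * w, self.c_out)
        self.grads["b"][...] = dflat.sum(axis=0)
        dxp = np.zeros_like(self._xp) if self.needs_dx else None
        for di in range(self.k):
            for dj in range(self.k):
                sl = np.ascontiguousarray(self._xp[:, di : di + h, dj : dj + w, :])
                self.grads["W"][di * self.k + dj][...] = (
                    sl.reshape(n * h * w, c).T @ dflat
                )
                if dxp is not None:
                    dsl = dflat @ self.params["W"][di * self.k + dj].T
                    dxp[:, di : di + h, dj : dj + w, :] += dsl.reshape(n, h, w, c)
        self._xp = None
        if dxp is None:
            return None
        return dxp[:, p : p + h, p : p + w, :]


class Conv1d(Layer):
    """Length-k same-padded convolution, stride 1, on (N, L, C) tensors."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        if k % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        std = np.sqrt(2.0 / (c_in * k))
        self.params = {
            "W": rng.normal(0.0, std, (k, c_in, c_out)).astype(F32),
            "b": np.zeros(c_out, dtype=F32),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self.needs_dx = True

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, l, c = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        self._xp = xp if train else None
        self._shape = x.shape
        out = np.tile(self.params["b"], (n * l, 1))
        for d in range(self.k):
            sl = np.ascontiguousarray(xp[:, d : d + l, :])
            out += sl.reshape(n * l, c) @ self.params["W"][d]
        return out.reshape(n, l, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, l, c = self._shape
        p = self.k // 2
        dflat = dout.reshape(n * l, self.c_out)
        self.grads["b"][...] = dflat.sum(axis=0)
        dxp = np.zeros_like(self._xp) if self.needs_dx else None
        for d in range(self.k):
            sl = np.ascontiguousarray(self._xp[:, d : d + l, :])
            self.grads["W"][d][...] = sl.reshape(n * l, c).T @ dflat
            if dxp is not None:
                dxp[:, d : d + l, :] += (dflat @ self.params["W"][d].T).reshape(n, l, c)
        self._xp = None
        if dxp is None:
            return None
        return dxp[:, p : p + l, :]


class BatchNorm(Layer):
    """Per-channel batch normalization; channels are the last axis."""

    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params = {
            "gamma": np.ones(n_channels, dtype=F32),
            "beta": np.zeros(n_channels, dtype=F32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(n_channels, dtype=F32)
        self.running_var = np.ones(n_channels, dtype=F32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            ).astype(F32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(F32)
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(F32)
        xhat = (x - mu) / std
        if train:
            self._xhat = xhat
            self._std = std
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = tuple(range(dout.ndim - 1))
        xhat, std = self._xhat, self._std
        self.grads["gamma"][...] = (dout * xhat).sum(axis=axes)
        self.grads["beta"][...] = dout.sum(axis=axes)
        g = self.params["gamma"] / std
        dx = g * (dout - dout.mean(axis=axes) - xhat * (dout * xhat).mean(axis=axes))
        self._xhat = None
        return dx.astype(F32, copy=False)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = F32(slope)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, self.slope * dout)


class MaxPool2d(Layer):
    """2x2, stride 2, channels-last (requires even spatial dims).

    Pooling runs as two staged pairwise maxima (columns then rows); the
    stored comparison masks route gradients to the first maximal element
    of each window, matching an argmax with earliest-index tie-breaking.
    """

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2d requires even spatial dimensions")
        a, b = x[:, :, 0::2, :], x[:, :, 1::2, :]
        mcol = a >= b
        m1 = np.where(mcol, a, b)  # (n, h, w/2, c)
        a2, b2 = m1[:, 0::2, :, :], m1[:, 1::2, :, :]
        mrow = a2 >= b2
        out = np.where(mrow, a2, b2)  # (n, h/2, w/2, c)
        if train:
            self._mcol, self._mrow = mcol, mrow
            self._shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        dm1 = np.zeros((n, h, w // 2, c), dtype=dout.dtype)
        dm1[:, 0::2] = np.where(self._mrow, dout, 0.0)
        dm1[:, 1::2] = np.where(self._mrow, 0.0, dout)
        dx = np.zeros((n, h, w, c), dtype=dout.dtype)
        dx[:, :, 0::2] = np.where(self._mcol, dm1, 0.0)
        dx[:, :, 1::2] = np.where(self._mcol, 0.0, dm1)
        self._mcol = self._mrow = None
        return dx


class MaxPool1d(Layer):
    """Size 2, stride 2, channels-last (requires even length)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, l, c = x.shape
        if l % 2:
            raise ValueError("MaxPool1d requires an even length")
        a, b = x[:, 0::2, :], x[:, 1::2, :]
        mask = a >= b
        if train:
            self._mask = mask
            self._shape = x.shape
        return np.where(mask, a, b)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, l, c = self._shape
        dx = np.zeros((n, l, c), dtype=dout.dtype)
        dx[:, 0::2] = np.where(self._mask, dout, 0.0)
        dx[:, 1::2] = np.where(self._mask, 0.0, dout)
        self._mask = None
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return np.ascontiguousarray(x).reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / n_in)
        self.params = {
            "W": rng.normal(0.0, std, (n_in, n_out)).astype(F32),
            "b": np.zeros(n_out, dtype=F32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"][...] = self._x.T @ dout
        self.grads["b"][...] = dout.sum(axis=0)
        dx = dout @ self.params["W"].T
        self._x = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not (0.0 <= p < 1.0):
            raise ValueError("dropout p must lie in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        mask = (self.rng.random(x.shape) >= self.p).astype(F32) / F32(1.0 - self.p)
        self._mask = mask
        return x * mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def param_items(self) -> list[tuple[Layer, str]]:
        return [(ly, k) for ly in self.layers for k in ly.params]

    def n_parameters(self) -> int:
        return sum(ly.params[k].size for ly, k in self.param_items())

    def get_weights(self) -> list[np.ndarray]:
        out = [ly.params[k].copy() for ly, k in self.param_items()]
        for ly in self.layers:
            if isinstance(ly, BatchNorm):
                out.append(ly.running_mean.copy())
                out.append(ly.running_var.copy())
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for ly, k in self.param_items():
            ly.params[k][...] = next(it)
        for ly in self.layers:
            if isinstance(ly, BatchNorm):
                ly.running_mean[...] = next(it)
                ly.running_var[...] = next(it)


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable binary cross-entropy on logits.

    Returns (mean loss, gradient wrt z).
    """
    z = z.astype(np.float64)
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    p = 1.0 / (1.0 + np.exp(-z))
    dz = (p - y) / z.shape[0]
    return float(loss.mean()), dz.astype(F32)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Adam:
    def __init__(
        self,
        net: Sequential,
        lr: float,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.net = net
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(ly.params[k]) for ly, k in net.param_items()]
        self.v = [np.zeros_like(ly.params[k]) for ly, k in net.param_items()]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (ly, k) in enumerate(self.net.param_items()):
            g = ly.grads[k]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            ly.params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(F32)
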