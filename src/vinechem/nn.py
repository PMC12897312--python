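"""Compact numpy implementation of the 1-D convolutional regression network.

Forward and backward passes are hand-coded per layer (no autograd). The
network is small enough — three conv blocks and three dense layers — that
explicit gradients stay readable, and the test suite includes a
finite-difference gradient check. All randomness (weight init, batch
shuffling, dropout masks) flows from a single seeded generator, so training
is bit-reproducible.

Layer chain: conv(16ch, k5, s2) - BN - ReLU - maxpool(w2, s1) -
conv(32ch, k3, s2) - BN - ReLU - maxpool(w2, s1) - conv(64ch, k1, s1) -
BN - ReLU - adaptive max-pool to length 1 - FC 64 (dropout 0.2) -
FC 32 (dropout 0.2) - FC 1; MSE loss, Adam optimizer.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class ArchitectureError(ValueError):
    pass


def _conv_len(length: int, kernel: int, stride: int) -> int:
    return (length - kernel) // stride + 1


def feature_map_lengths(input_length: int) -> tuple[int, ...]:
    """Sequence of feature-map lengths through the conv/pool stack.

    Returns (conv1, pool1, conv2, pool2, conv3, adaptive) lengths; raises if
    any stage collapses to a non-positive length.
    """
    lengths = []
    length = _conv_len(input_length, 5, 2); lengths.append(length)   # conv1
    length = length - 1; lengths.append(length)                      # pool w2 s1
    length = _conv_len(length, 3, 2); lengths.append(length)         # conv2
    length = length - 1; lengths.append(length)                      # pool w2 s1
    lengths.append(length)                                           # conv3 k1 s1
    lengths.append(1)                                                # adaptive pool
    if any(l < 1 for l in lengths):
        raise ArchitectureError(
            f"input length {input_length} collapses inside the network; "
            "minimum supported length is 15"
        )
    return tuple(lengths)


class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []


class Conv1d(_Layer):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.kernel, self.stride = kernel, stride
        bound = 1.0 / np.sqrt(c_in * kernel)
        self.W = rng.uniform(-bound, bound, size=(c_out, c_in, kernel))
        self.b = rng.uniform(-bound, bound, size=c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        # x: (N, C_in, L); windows: (N, C_in, L_out, k)
        xw = sliding_window_view(x, self.kernel, axis=2)[:, :, :: self.stride, :]
        self._xw, self._xshape = xw, x.shape
        return np.einsum("nclk,ock->nol", xw, self.W) + self.b[None, :, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = np.einsum("nol,nclk->ock", gy, self._xw)
        self.grads[1][...] = gy.sum(axis=(0, 2))
        gx_win = np.einsum("nol,ock->nclk", gy, self.W)
        gx = np.zeros(self._xshape)
        l_out = gy.shape[2]
        for j in range(self.kernel):
            gx[:, :, j : j + self.stride * l_out : self.stride] += gx_win[..., j]
        return gx


class BatchNorm1d(_Layer):
    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        x_hat = (x - mean[None, :, None]) / std[None, :, None]
        self._x_hat, self._std, self._training = x_hat, std, training
        return self.gamma[None, :, None] * x_hat + self.beta[None, :, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x_hat, std = self._x_hat, self._std
        self.grads[0][...] = (gy * x_hat).sum(axis=(0, 2))
        self.grads[1][...] = gy.sum(axis=(0, 2))
        g = self.gamma[None, :, None] / std[None, :, None]
        if not self._training:
            return g * gy
        m = gy.shape[0] * gy.shape[2]
        mean_gy = gy.mean(axis=(0, 2), keepdims=True)
        mean_gy_xhat = (gy * x_hat).mean(axis=(0, 2), keepdims=True)
        return g * (gy - mean_gy - x_hat * mean_gy_xhat)


class ReLU(_Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class MaxPoolW2S1(_Layer):
    """Max pooling with window 2 and stride 1 (length shrinks by one)."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        left, right = x[..., :-1], x[..., 1:]
        self._left_wins = left >= right  # ties take the left element
        self._xshape = x.shape
        return np.where(self._left_wins, left, right)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = np.zeros(self._xshape)
        gx[..., :-1] += gy * self._left_wins
        gx[..., 1:] += gy * ~self._left_wins
        return gx


class GlobalMaxPool(_Layer):
    """Adaptive max pooling to output length 1."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._arg = x.argmax(axis=2)
        self._xshape = x.shape
        return x.max(axis=2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = np.zeros(self._xshape)
        n, c = self._arg.shape
        ni, ci = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        gx[ni, ci, self._arg] = gy
        return gx


class Linear(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        bound = 1.0 / np.sqrt(n_in)
        self.W = rng.uniform(-bound, bound, size=(n_out, n_in))
        self.b = rng.uniform(-bound, bound, size=n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = gy.T @ self._x
        self.grads[1][...] = gy.sum(axis=0)
        return gy @ self.W


class Dropout(_Layer):
    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy if self._mask is None else gy * self._mask


class Flatten(_Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return x  # GlobalMaxPool already yields (N, C)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy


class SpectralCNN:
    """The fixed regression architecture over 1-D spectra."""

    def __init__(self, input_length: int, seed: int = 0,
                 dropout: float = 0.2) -> None:
        feature_map_lengths(input_length)  # validates the length
        self.input_length = input_length
        self.rng = np.random.default_rng(seed)
        r = self.rng
        self.layers: list[_Layer] = [
            Conv1d(1, 16, kernel=5, stride=2, rng=r), BatchNorm1d(16), ReLU(),
            MaxPoolW2S1(),
            Conv1d(16, 32, kernel=3, stride=2, rng=r), BatchNorm1d(32), ReLU(),
            MaxPoolW2S1(),
            Conv1d(32, 64, kernel=1, stride=1, rng=r), BatchNorm1d(64), ReLU(),
            GlobalMaxPool(),
            Linear(64, 64, rng=r), Dropout(dropout, r), ReLU(),
            Linear(64, 32, rng=r), Dropout(dropout, r), ReLU(),
            Linear(32, 1, rng=r),
        ]

    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        """X: (N, L) standardized spectra -> (N,) predictions."""
        if X.ndim != 2 or X.shape[1] != self.input_length:
            raise ArchitectureError(
                f"expected (n, {self.input_length}) input, got {X.shape}"
            )
        h = X[:, None, :]
        for layer in self.layers:
            h = layer.forward(h, training)
        return h.ravel()

    def backward(self, grad_out: np.ndarray) -> None:
        g = grad_out[:, None]
        for layer in reversed(self.layers):
            g = layer.backward(g)


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
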