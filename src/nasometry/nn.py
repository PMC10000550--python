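"""Minimal CPU conv-net building blocks for landmark regression.

Implements exactly the layer types the detector architecture needs — 2D
convolution (stride 1, 'same' padding), batch normalization, ReLU, 2×2/2 max
pooling, dense layers — with hand-written backpropagation and an Adam
optimizer, all on float32 numpy arrays.

Activations are kept in NHWC layout (channels contiguous): convolutions then
reduce to a single BLAS sgemm over an im2col patch matrix whose gather/
scatter copies run over contiguous channel runs, which is what makes
training the full architecture at 128×128 practical on one CPU core.

All parameter initialization is drawn from a ``numpy.random.Generator``, so
training is bit-reproducible under a seed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["Layer", "Conv2D", "BatchNorm2D", "ReLU", "MaxPool2x2", "Flatten", "Dense", "Sequential", "Adam", "mse_loss"]


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """k×k convolution on NHWC input, stride 1, 'same' padding, He init.

    Weight layout is (k·k·C, F): one gemm computes all output pixels.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator, dtype=np.float32):
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.k = kernel
        self.pad = kernel // 2
        scale = np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.w = (rng.standard_normal((kernel * kernel * in_ch, out_ch)) * scale).astype(dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        p = self.pad
        xpad = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xpad, (self.k, self.k), axis=(1, 2))
        # (N, H, W, C, kh, kw) -> (N, H, W, kh, kw, C): innermost copies are
        # contiguous channel runs
        return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(n * h * w, -1)

    def forward(self, x, training):
        n, h, w, _ = x.shape
        cols = self._im2col(x)
        self._cols = cols if training else None
        out = cols @ self.w
        out += self.b
        return out.reshape(n, h, w, self.out_ch)

    def backward(self, dout):
        n, h, w, f = dout.shape
        c = self.in_ch
        p = self.pad
        dflat = dout.reshape(-1, f)
        self.db[:] = dflat.sum(axis=0)
        np.matmul(self._cols.T, dflat, out=self.dw)
        dcols = (dflat @ self.w.T).reshape(n, h, w, self.k, self.k, c)
        dxpad = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=dout.dtype)
        for i in range(self.k):
            for j in range(self.k):
                dxpad[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        self._cols = None
        if p:
            return dxpad[:, p:-p, p:-p, :]
        return dxpad


class BatchNorm2D(Layer):
    """Per-channel batch normalization over (N, H, W) with running stats."""

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5, dtype=np.float32):
        self.gamma = np.ones(ch, dtype=dtype)
        self.beta = np.zeros(ch, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, training):
        axes = (0, 1, 2)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean + (1 - self.momentum) * mean).astype(x.dtype)
            self.running_var = (self.momentum * self.running_var + (1 - self.momentum) * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mean) * inv
        if training:
            self._cache = (xhat, inv)
        return self.gamma * xhat + self.beta

    def backward(self, dout):
        xhat, inv = self._cache
        axes = (0, 1, 2)
        m = dout.shape[0] * dout.shape[1] * dout.shape[2]
        self.dgamma[:] = (dout * xhat).sum(axis=axes)
        self.dbeta[:] = dout.sum(axis=axes)
        dxhat = dout * self.gamma
        # standard batch-norm backward, vectorized per channel
        dx = (inv / m) * (m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes))
        self._cache = None
        return dx.astype(dout.dtype)


class ReLU(Layer):
    def forward(self, x, training):
        out = np.maximum(x, 0)
        self._mask = x > 0 if training else None
        return out

    def backward(self, dout):
        out = dout * self._mask
        self._mask = None
        return out


class MaxPool2x2(Layer):
    """2×2 max pooling with stride 2 (NHWC); gradient to the first argmax."""

    def forward(self, x, training):
        n, h, w, c = x.shape
        assert h % 2 == 0 and w % 2 == 0, "spatial dims must be even for 2x2/2 pooling"
        xr = np.ascontiguousarray(
            x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        ).reshape(n, h // 2, w // 2, c, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if training:
            self._idx = idx
            self._in_shape = (n, h, w, c)
        return out

    def backward(self, dout):
        n, h, w, c = self._in_shape
        dxr = np.zeros((n, h // 2, w // 2, c, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dx = dxr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(n, h, w, c)
        self._idx = None
        return np.ascontiguousarray(dx)


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, training):
        self._x = x if training else None
        return x @ self.w + self.b

    def backward(self, dout):
        np.matmul(self._x.T, dout, out=self.dw)
        self.db[:] = dout.sum(axis=0)
        dx = dout @ self.w.T
        self._x = None
        return dx


class Sequential:
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All learnable parameters plus batch-norm running stats."""
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params()):
                out[f"layer{i}_param{j}"] = p
            if isinstance(layer, BatchNorm2D):
                out[f"layer{i}_running_mean"] = layer.running_mean
                out[f"layer{i}_running_var"] = layer.running_var
        return out

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for key, target in self.state_arrays().items():
            target[...] = arrays[key]


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all outputs; returns (loss, dpred)."""
    diff = pred - target
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    return loss, (2.0 / diff.size) * diff.astype(pred.dtype)


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 0.001, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * (g * g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
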