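"""Minimal NumPy neural-network layers with explicit backprop.

Layers operate on NHWC float32 batches. Convolutions are evaluated as a
single BLAS matmul per layer via an im2col view (``sliding_window_view``);
their input gradient is computed as a full correlation with the transposed
kernel, which is again one matmul. This keeps a depth-3 U-Net trainable on
one CPU core in minutes.

Each layer caches what its backward pass needs on ``forward`` and
accumulates parameter gradients into ``.grads`` (zeroed by the optimizer
step). No autograd, no graph: the model wires backward calls by hand.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "ConvTranspose2x2",
    "Dense",
    "MaxPool2x2",
    "relu",
    "relu_backward",
    "sigmoid",
    "softmax",
    "Adam",
]


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape).astype(np.float32)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H+k-1, W+k-1, C) padded input -> (N*H*W, C*k*k) patch matrix."""
    n, hp, wp, c = x.shape
    h, w = hp - k + 1, wp - k + 1
    v = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    # v: (N, H, W, C, k, k) -> (N*H*W, k*k*C) with kernel-major ordering
    return np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3)).reshape(
        n * h * w, k * k * c
    )


class Conv2d:
    """k x k same-padded convolution, NHWC, stride 1."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.w = _he_init(rng, (k * k * c_in, c_out), k * k * c_in)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.grads = {"w": np.zeros_like(self.w), "b": np.zeros_like(self.b)}
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    @property
    def params(self):
        return {"w": self.w, "b": self.b}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, _ = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        cols = _im2col(xp, self.k)
        if train:
            self._cols, self._shape = cols, x.shape
        return (cols @ self.w + self.b).reshape(n, h, w, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, _ = dout.shape
        dflat = dout.reshape(n * h * w, self.c_out)
        self.grads["w"] += self._cols.T @ dflat
        self.grads["b"] += dflat.sum(axis=0)
        # dx = full correlation of dout with spatially flipped, transposed kernel
        wk = self.w.reshape(self.k, self.k, self.c_in, self.c_out)
        wflip = wk[::-1, ::-1].transpose(0, 1, 3, 2).reshape(
            self.k * self.k * self.c_out, self.c_in
        )
        p = self.k // 2
        dpad = np.pad(dout, ((0, 0), (p, p), (p, p), (0, 0))) if p else dout
        dx = (_im2col(dpad, self.k) @ wflip).reshape(self._shape)
        self._cols = None
        return dx


class ConvTranspose2x2:
    """2x2 transposed convolution with stride 2 (non-overlapping upsample)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        self.w = _he_init(rng, (c_in, 4 * c_out), c_in)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.grads = {"w": np.zeros_like(self.w), "b": np.zeros_like(self.b)}
        self._x: np.ndarray | None = None

    @property
    def params(self):
        return {"w": self.w, "b": self.b}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, _ = x.shape
        if train:
            self._x = x
        y = (x.reshape(n * h * w, self.c_in) @ self.w).reshape(
            n, h, w, 2, 2, self.c_out
        )
        y = y.transpose(0, 1, 3, 2, 4, 5).reshape(n, 2 * h, 2 * w, self.c_out)
        return y + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h2, w2, _ = dout.shape
        h, w = h2 // 2, w2 // 2
        d = dout.reshape(n, h, 2, w, 2, self.c_out).transpose(0, 1, 3, 2, 4, 5)
        dflat = d.reshape(n * h * w, 4 * self.c_out)
        xflat = self._x.reshape(n * h * w, self.c_in)
        self.grads["w"] += xflat.T @ dflat
        self.grads["b"] += dout.sum(axis=(0, 1, 2))
        dx = (dflat @ self.w.T).reshape(self._x.shape)
        self._x = None
        return dx


class MaxPool2x2:
    """2x2 max pooling, stride 2; backward routes to the argmax position."""

    def __init__(self):
        self._mask: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    params = {}
    grads = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        y = xr.max(axis=(2, 4))
        if train:
            self._mask = xr == y[:, :, None, :, None, :]
            self._shape = x.shape
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        # ties (rare with float noise) split the gradient; acceptable
        counts = self._mask.sum(axis=(2, 4), keepdims=True)
        d = self._mask * (dout[:, :, None, :, None, :] / counts)
        dx = d.reshape(self._shape)
        self._mask = None
        return dx


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = _he_init(rng, (d_in, d_out), d_in)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.grads = {"w": np.zeros_like(self.w), "b": np.zeros_like(self.b)}
        self._x: np.ndarray | None = None

    @property
    def params(self):
        return {"w": self.w, "b": self.b}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["w"] += self._x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        dx = dout @ self.w.T
        self._x = None
        return dx


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_backward(dout: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Gradient through ReLU given its *output* y."""
    return dout * (y > 0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Adam:
    """Adam over a list of layers with ``params``/``grads`` dicts."""

    def __init__(self, layers, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for li, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m = self.m[li][k]
                v = self.v[li][k]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for layer in self.layers:
            for g in layer.grads.values():
                g[...] = 0.0
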