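"""Minimal, deterministic 2D-CNN layer engine on numpy.

Implements exactly the primitives the beat classifiers need: same-padded
2D convolution (im2col + BLAS matmul), 2x2/stride-2 max pooling, batch
normalization, dense layers, ReLU, a fused softmax cross-entropy loss
and the Adam optimizer.  All computation is float32 numpy, so training
is bit-reproducible given a seed — there is no backend nondeterminism
to pin.  Gradients are verified against numerical differentiation in
the test suite.

Tensor layout is NCHW (batch, channels, rows, cols).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Layer", "Conv2D", "MaxPool2D", "BatchNorm", "ReLU", "Flatten",
    "Dense", "Identity", "Sequential", "Adam", "softmax", "softmax_cross_entropy",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)


class Layer:
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def params(self) -> list[Param]:
        return []

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        return in_shape


def _same_pad(k: int) -> tuple[int, int]:
    # TF "same" convention: total pad k-1, smaller half first
    before = (k - 1) // 2
    return before, k - 1 - before


class Conv2D(Layer):
    """Same-padded 2D convolution with square kernels, stride 1."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator | None = None):
        self.in_channels, self.out_channels, self.kernel = in_channels, out_channels, kernel
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, fan_in))
        self.w = Param(w)
        self.b = Param(np.zeros(out_channels))
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return [self.w, self.b]

    def out_shape(self, in_shape):
        c, h, w = in_shape
        return (self.out_channels, h, w)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        p0, p1 = _same_pad(k)
        xp = np.pad(x, ((0, 0), (0, 0), (p0, p1), (p0, p1)))
        # (N, C, H, W, k, k) view without copying
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        n, c, h, w = x.shape
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        return np.ascontiguousarray(cols, dtype=np.float32)

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        cols = self._im2col(x)
        out = cols @ self.w.data.T + self.b.data
        self._cache = (cols, x.shape)
        return out.reshape(n, h, w, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, (n, c, h, w) = self._cache
        k = self.kernel
        d2 = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_channels)
        d2 = np.ascontiguousarray(d2, dtype=np.float32)
        self.w.grad[...] = d2.T @ cols
        self.b.grad[...] = d2.sum(axis=0)
        dcols = (d2 @ self.w.data).reshape(n, h, w, c, k, k)
        p0, p1 = _same_pad(k)
        dxp = np.zeros((n, c, h + k - 1, w + k - 1), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p0 : p0 + h, p0 : p0 + w]


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2, valid (trailing odd row/col dropped)."""

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : h2 * 2, : w2 * 2].reshape(n, c, h2, 2, w2, 2)
        win = xc.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self._arg = win.argmax(axis=-1)
        self._in_shape = x.shape
        return win.max(axis=-1)

    def backward(self, dout):
        n, c, h, w = self._in_shape
        h2, w2 = h // 2, w // 2
        dwin = np.zeros((n, c, h2, w2, 4), dtype=np.float32)
        np.put_along_axis(dwin, self._arg[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dx[:, :, : h2 * 2, : w2 * 2] = (
            dwin.reshape(n, c, h2, w2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h2 * 2, w2 * 2)
        )
        return dx

    def out_shape(self, in_shape):
        c, h, w = in_shape
        return (c, h // 2, w // 2)


class BatchNorm(Layer):
    """Batch normalization over (N,) for dense or (N, H, W) for conv input."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_features))
        self.beta = Param(np.zeros(n_features))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(n_features, dtype=np.float32)
        self.running_var = np.ones(n_features, dtype=np.float32)

    @property
    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0, 2, 3)

    def _shape(self, x):
        return (1, -1) if x.ndim == 2 else (1, -1, 1, 1)

    def forward(self, x, training=False):
        s = self._shape(x)
        if training:
            axes = self._axes(x)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(np.float32)
        xhat = (x - mean.reshape(s)) / std.reshape(s)
        self._cache = (xhat, std, s)
        return (self.gamma.data.reshape(s) * xhat + self.beta.data.reshape(s)).astype(np.float32)

    def backward(self, dout):
        xhat, std, s = self._cache
        axes = (0,) if dout.ndim == 2 else (0, 2, 3)
        m = float(np.prod([dout.shape[a] for a in axes]))
        dg = (dout * xhat).sum(axis=axes)
        db = dout.sum(axis=axes)
        self.gamma.grad[...] = dg
        self.beta.grad[...] = db
        g = self.gamma.data.reshape(s)
        return (g / std.reshape(s) / m) * (
            m * dout - db.reshape(s) - xhat * dg.reshape(s)
        ).astype(np.float32)


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0).astype(np.float32)


class Flatten(Layer):
    def forward(self, x, training=False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._in_shape)

    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    @property
    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w.data + self.b.data

    def backward(self, dout):
        self.w.grad[...] = self._x.T @ dout
        self.b.grad[...] = dout.sum(axis=0)
        return dout @ self.w.data.T

    def out_shape(self, in_shape):
        return (self.w.data.shape[1],)


class Identity(Layer):
    """Structural no-op (used where an architecture table prints a layer
    that has no effect on a flat vector)."""

    def __init__(self, note: str = ""):
        self.note = note

    def forward(self, x, training=False):
        return x

    def backward(self, dout):
        return dout


class Sequential:
    """An ordered layer stack producing logits."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def num_params(self) -> int:
        return int(sum(p.data.size for p in self.params))

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All tensors needed to restore the network (weights + BN stats)."""
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                out[f"layer{i}_param{j}"] = p.data
            if isinstance(layer, BatchNorm):
                out[f"layer{i}_running_mean"] = layer.running_mean
                out[f"layer{i}_running_var"] = layer.running_var
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                p.data = np.asarray(state[f"layer{i}_param{j}"], dtype=np.float32)
                p.grad = np.zeros_like(p.data)
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.asarray(state[f"layer{i}_running_mean"], dtype=np.float32)
                layer.running_var = np.asarray(state[f"layer{i}_running_var"], dtype=np.float32)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy of integer targets; returns (loss, dlogits, probs)."""
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    loss = max(float(-np.mean(np.log(probs[np.arange(n), targets] + 1e-12))), 0.0)
    dlogits = probs.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return loss, (dlogits / n).astype(np.float32), probs


class Adam:
    """Adam optimizer with bias correction (lr 1e-3, betas 0.9/0.999)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
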