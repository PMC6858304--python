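"""Neural-network layers with explicit forward/backward passes.

All layers operate on float32 arrays in NHWC layout (batch, height, width,
channels). Each layer caches what its backward pass needs during forward;
state is overwritten on every call, so a layer instance belongs to exactly
one network. The backward pass accepts a ``guided`` flag that switches every
rectifier to the guided-backpropagation rule (gradients are additionally
gated on their own sign), which is how the saliency module reuses the same
graph.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "Dense",
    "ReLU",
    "MaxPool2",
    "AvgPool2",
    "GlobalAvgPool",
    "Dropout",
    "Flatten",
]

class Layer:
    """Base class; stateless layers only implement forward/backward."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray, guided: bool = False) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def set_rng(self, rng: np.random.Generator) -> None:  # noqa: B027
        """Hook for stochastic layers (dropout); default is a no-op."""


class Conv2D(Layer):
    """Valid (no padding), stride-1 2-D convolution.

    Weights are stored as a ``(k, k, c_in, c_out)`` tensor. Forward and both
    backward products are computed by kernel-offset accumulation — one GEMM
    per kernel tap on a contiguous shifted slice — which on CPU is markedly
    faster and leaner than materialising a full im2col matrix. The input
    gradient is the full correlation of the output gradient with the
    180-degree-rotated kernel.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3,
                 rng: np.random.Generator | None = None):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        rng = rng or np.random.default_rng()
        fan_in = k * k * c_in
        scale = np.sqrt(2.0 / fan_in)  # He init for rectified nets
        self.W = (rng.standard_normal((k, k, c_in, c_out)) * scale).astype(
            np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[1] < self.k or x.shape[2] < self.k:
            raise ValueError(
                f"Conv2D(k={self.k}): input spatial size {x.shape[1:3]} too small"
            )
        self._x = x
        n, h, w, _ = x.shape
        k = self.k
        ho, wo = h - k + 1, w - k + 1
        out = np.zeros((n, ho, wo, self.c_out), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                np.add(out, x[:, di:di + ho, dj:dj + wo, :] @ self.W[di, dj],
                       out=out)
        out += self.b
        return out

    def backward(self, dout: np.ndarray, guided: bool = False,
                 compute_dx: bool = True) -> np.ndarray | None:
        x = self._x
        if x is None:
            raise RuntimeError("backward() before forward()")
        n, h, w, _ = x.shape
        k = self.k
        ho, wo = dout.shape[1], dout.shape[2]
        d_flat = np.ascontiguousarray(dout).reshape(-1, self.c_out)
        for di in range(k):
            for dj in range(k):
                xs = np.ascontiguousarray(
                    x[:, di:di + ho, dj:dj + wo, :]).reshape(-1, self.c_in)
                self.dW[di, dj] = xs.T @ d_flat
        self.db[...] = d_flat.sum(axis=0)
        if not compute_dx:
            return None
        pad = k - 1
        dpad = np.pad(dout, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        dx = np.zeros_like(x)
        for di in range(k):
            for dj in range(k):
                # rotated kernel, output channels contracted
                wk = self.W[k - 1 - di, k - 1 - dj].T
                np.add(dx, dpad[:, di:di + h, dj:dj + w, :] @ wk, out=dx)
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / d_in)
        self.W = (rng.standard_normal((d_in, d_out)) * scale).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout, guided=False):
        if self._x is None:
            raise RuntimeError("backward() before forward()")
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32, copy=False)

    def backward(self, dout, guided=False):
        d = dout * self._mask
        if guided:
            # Guided backprop: also discard negative upstream gradients.
            d = np.where(d > 0, d, 0.0).astype(np.float32, copy=False)
        return d


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        xc = x[:, :h2 * 2, :w2 * 2]
        r = xc.reshape(n, h2, 2, w2, 2, c)
        out = r.max(axis=(2, 4))
        flat = r.transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, 4)
        self._arg = flat.argmax(axis=-1)
        return out

    def backward(self, dout, guided=False):
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        flat = np.zeros((n, h2, w2, c, 4), dtype=np.float32)
        np.put_along_axis(flat, self._arg[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, h, w, c), dtype=np.float32)
        dx[:, :h2 * 2, :w2 * 2] = (
            flat.reshape(n, h2, w2, c, 2, 2)
                .transpose(0, 1, 4, 2, 5, 3)
                .reshape(n, h2 * 2, w2 * 2, c)
        )
        return dx


class AvgPool2(Layer):
    """2x2 average pooling, stride 2; odd trailing rows/columns dropped."""

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        out = x[:, :h2 * 2, :w2 * 2].reshape(n, h2, 2, w2, 2, c).mean(axis=(2, 4))
        return out.astype(np.float32, copy=False)

    def backward(self, dout, guided=False):
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        dx = np.zeros((n, h, w, c), dtype=np.float32)
        spread = np.repeat(np.repeat(dout, 2, axis=1), 2, axis=2) * 0.25
        dx[:, :h2 * 2, :w2 * 2] = spread
        return dx


class GlobalAvgPool(Layer):
    """Average over the spatial axes: (N, H, W, C) -> (N, C)."""

    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout, guided=False):
        n, h, w, c = self._in_shape
        return np.broadcast_to(
            dout[:, None, None, :] / (h * w), (n, h, w, c)
        ).astype(np.float32)


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, p: float = 0.25):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self._rng = np.random.default_rng()
        self._mask: np.ndarray | None = None

    def set_rng(self, rng):
        self._rng = rng

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self._rng.random(x.shape) >= self.p).astype(np.float32)
        return x * self._mask / (1.0 - self.p)

    def backward(self, dout, guided=False):
        if self._mask is None:
            return dout
        return dout * self._mask / (1.0 - self.p)


class DenseBlock(Layer):
    """Densely connected convolutional block.

    Each internal 3x3 convolution (applied with same-padding) sees the
    channel-wise concatenation of the block input and every earlier internal
    output, and contributes ``growth`` new channels; the block output is the
    full concatenation, so it has ``c_in + n_layers * growth`` channels at
    the input's spatial size.
    """

    def __init__(self, c_in: int, n_layers: int, growth: int,
                 rng: np.random.Generator | None = None):
        self.c_in, self.n_layers, self.growth = c_in, n_layers, growth
        self.convs = [Conv2D(c_in + i * growth, growth, 3, rng=rng)
                      for i in range(n_layers)]
        self.relus = [ReLU() for _ in range(n_layers)]

    @property
    def c_out(self) -> int:
        return self.c_in + self.n_layers * self.growth

    def forward(self, x, train=False):
        feats = x
        for conv, relu in zip(self.convs, self.relus):
            padded = np.pad(feats, ((0, 0), (1, 1), (1, 1), (0, 0)))
            y = relu.forward(conv.forward(padded, train=train), train=train)
            feats = np.concatenate([feats, y], axis=-1)
        return feats

    def backward(self, dout, guided=False):
        d = dout
        for conv, relu in zip(self.convs[::-1], self.relus[::-1]):
            d_prev, d_y = d[..., :-self.growth], d[..., -self.growth:]
            d_pad = conv.backward(relu.backward(d_y, guided=guided),
                                  guided=guided)
            d = np.ascontiguousarray(d_prev) + d_pad[:, 1:-1, 1:-1, :]
        return d

    def params(self):
        return [p for c in self.convs for p in c.params()]

    def grads(self):
        return [g for c in self.convs for g in c.grads()]


class Flatten(Layer):
    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout, guided=False):
        return dout.reshape(self._in_shape)
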