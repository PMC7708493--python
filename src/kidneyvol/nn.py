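"""Minimal numpy layers with explicit forward/backward passes.

Everything operates on single samples laid out channels-last, ``(H, W, C)``
(batch size one throughout, matching the training configuration). Each layer
caches what its backward pass needs; a layer instance is used once per
forward pass. Convolutions use an im2col formulation so the heavy lifting is
a single matmul.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "MaxPool2", "Upsample2", "ResBlock", "softmax", "softmax_cross_entropy", "Adam"]


class Layer:
    """Base: parameterized layers expose .params/.grads dicts."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}


class Conv2d(Layer):
    """k x k same-padding convolution, stride 1, optional fused ReLU."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng: np.random.Generator | None = None,
                 relu: bool = False):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cin, self.cout, self.k, self.relu = cin, cout, k, relu
        fan_in = k * k * cin
        scale = np.sqrt(2.0 / fan_in)  # He initialization
        self.params["W"] = rng.normal(0.0, scale, size=(fan_in, cout)).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        H, W, C = x.shape
        k, p = self.k, self.k // 2
        if k == 1:
            return x.reshape(H, W, C)
        xp = np.pad(x, ((p, p), (p, p), (0, 0)))
        cols = np.empty((H, W, k * k, C), dtype=x.dtype)
        n = 0
        for di in range(k):
            for dj in range(k):
                cols[:, :, n, :] = xp[di : di + H, dj : dj + W, :]
                n += 1
        return cols.reshape(H, W, k * k * C)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        cols = self._im2col(x)
        self._cols = cols
        y = cols @ self.params["W"] + self.params["b"]
        if self.relu:
            self._mask = y > 0
            y *= self._mask
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.relu:
            dout = dout * self._mask
        H, W, _ = dout.shape
        kkC = self.k * self.k * self.cin
        dcols_flat = dout.reshape(-1, self.cout)
        self.grads["W"] = self._cols.reshape(-1, kkC).T @ dcols_flat
        self.grads["b"] = dcols_flat.sum(axis=0)
        dcols = (dout @ self.params["W"].T).reshape(H, W, self.k * self.k, self.cin)
        if self.k == 1:
            return dcols.reshape(H, W, self.cin)
        p = self.k // 2
        dxp = np.zeros((H + 2 * p, W + 2 * p, self.cin), dtype=dout.dtype)
        n = 0
        for di in range(self.k):
            for dj in range(self.k):
                dxp[di : di + H, dj : dj + W, :] += dcols[:, :, n, :]
                n += 1
        return dxp[p : p + H, p : p + W, :]


class MaxPool2:
    """2x2 max pooling; input dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        H, W, C = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"max-pool needs even dims, got {x.shape}")
        blocks = x.reshape(H // 2, 2, W // 2, 2, C)
        y = blocks.max(axis=(1, 3))
        self._mask = blocks == y[:, None, :, None, :]
        self._in_shape = x.shape
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        H, W, C = self._in_shape
        # split gradient evenly among tied maxima
        counts = self._mask.sum(axis=(1, 3), keepdims=True)
        d = self._mask * (dout[:, None, :, None, :] / counts)
        return d.reshape(H, W, C)


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return np.repeat(np.repeat(x, 2, axis=0), 2, axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        H, W, C = self._in_shape
        return dout.reshape(H, 2, W, 2, C).sum(axis=(1, 3))


class ResBlock(Layer):
    """conv-relu-conv with an identity (or 1x1-projected) short skip, then ReLU.

    The additive shortcut around the two-convolution block is the
    ResNet-style short skip; a 1x1 projection is inserted when the channel
    count changes.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, rng, relu=True)
        self.conv2 = Conv2d(cout, cout, 3, rng, relu=False)
        self.proj = Conv2d(cin, cout, 1, rng, relu=False) if cin != cout else None
        self.children = [c for c in (self.conv1, self.conv2, self.proj) if c is not None]

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.conv2.forward(self.conv1.forward(x))
        s = self.proj.forward(x) if self.proj is not None else x
        y = h + s
        self._mask = y > 0
        return y * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = dout * self._mask
        dx = self.conv1.backward(self.conv2.backward(dout))
        if self.proj is not None:
            dx = dx + self.proj.backward(dout)
        else:
            dx = dx + dout
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean pixel-wise cross-entropy; returns (loss, dlogits)."""
    p = softmax(logits)
    n = labels.size
    eps = 1e-12
    ll = np.log(np.take_along_axis(p, labels[..., None], axis=-1) + eps)
    loss = -float(ll.mean())
    dlogits = p.copy()
    np.put_along_axis(
        dlogits, labels[..., None],
        np.take_along_axis(dlogits, labels[..., None], axis=-1) - 1.0, axis=-1
    )
    return loss, dlogits / n


class Adam:
    """Adam over a list of (layer, name) parameter slots."""

    def __init__(self, slots, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.slots = list(slots)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[name]) for layer, name in self.slots]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in self.slots]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (layer, name) in enumerate(self.slots):
            g = layer.grads[name]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            layer.params[name] -= self.lr * (self.m[i] / b1t) / (
                np.sqrt(self.v[i] / b2t) + self.eps
            )
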