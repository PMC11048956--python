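"""A compact NumPy layer framework for 1-D sequence CNNs.

Implements exactly the operations the splice-site network needs — stride-1
1-D convolution, batch normalization, ReLU, non-overlapping average pooling,
efficient channel attention (ECA), global average pooling and a dense head —
each with an explicit backward pass, so the same code serves training
(SGD + Nesterov momentum), input-gradient attribution and Grad-CAM.

Tensor convention: activations are ``(batch, length, channels)`` float32.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv1D",
    "BatchNorm",
    "ReLU",
    "AvgPool",
    "GlobalAvgPool",
    "Dense",
    "ECA",
    "Sequential",
    "Residual",
    "softmax",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Layer:
    """Base layer: parameter dict, gradient dict, forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.capture = False  # when True, cache output and output-gradient

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def layers(self):
        """Iterate primitive sub-layers (self for primitives)."""
        yield self

    def zero_grads(self) -> None:
        for layer in self.layers():
            for k, v in layer.params.items():
                layer.grads[k] = np.zeros_like(v)


class Conv1D(Layer):
    """Stride-1 1-D convolution with 'same' zero padding along positions.

    Weight shape ``(k, cin, cout)``; each output position sees ``k`` input
    positions across all input channels.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 bias: bool = True) -> None:
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        std = np.sqrt(2.0 / (k * cin))  # He initialization for ReLU nets
        self.params["W"] = rng.normal(0.0, std, size=(k, cin, cout)).astype(np.float32)
        if bias:
            self.params["b"] = np.zeros(cout, dtype=np.float32)
        self.use_bias = bias

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, L, _ = x.shape
        k = self.k
        left, right = (k - 1) // 2, k // 2
        xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
        # (B, L, cin, k) -> (B, L, k, cin)
        cols = sliding_window_view(xp, k, axis=1).transpose(0, 1, 3, 2)
        self._cols = cols.reshape(B * L, k * self.cin)
        self._shape = (B, L)
        W = self.params["W"].reshape(k * self.cin, self.cout)
        y = self._cols @ W
        y = y.reshape(B, L, self.cout)
        if self.use_bias:
            y = y + self.params["b"]
        if self.capture:
            self.last_output = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.capture:
            self.grad_output = dy
        B, L = self._shape
        k = self.k
        dy_flat = dy.reshape(B * L, self.cout)
        self.grads["W"] += (self._cols.T @ dy_flat).reshape(k, self.cin, self.cout)
        if self.use_bias:
            self.grads["b"] += dy_flat.sum(axis=0)
        W = self.params["W"].reshape(k * self.cin, self.cout)
        dcols = (dy_flat @ W.T).reshape(B, L, k, self.cin)
        left = (k - 1) // 2
        dxp = np.zeros((B, L + k - 1, self.cin), dtype=dy.dtype)
        for j in range(k):
            dxp[:, j : j + L, :] += dcols[:, :, j, :]
        return dxp[:, left : left + L, :]


class BatchNorm(Layer):
    """Batch normalization over (batch, position) per channel.

    Training mode uses batch statistics and updates moving statistics;
    inference mode uses the moving statistics (an affine map), which keeps
    attribution and Grad-CAM deterministic.
    """

    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.9) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        # moving statistics are state, not trained parameters
        self.moving_mean = np.zeros(c, dtype=np.float32)
        self.moving_var = np.ones(c, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.moving_mean = (
                self.momentum * self.moving_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.moving_var = (
                self.momentum * self.moving_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.moving_mean, self.moving_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        self._training = training
        self._n = x.shape[0] * x.shape[1]
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 1))
        self.grads["beta"] += dy.sum(axis=(0, 1))
        g = self.params["gamma"]
        if not self._training:
            return dy * g * inv_std
        n = self._n
        dxhat = dy * g
        return (
            inv_std
            / n
            * (n * dxhat - dxhat.sum(axis=(0, 1)) - xhat * (dxhat * xhat).sum(axis=(0, 1)))
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class AvgPool(Layer):
    """Non-overlapping average pooling of window ``p`` along positions;
    a remainder shorter than ``p`` is truncated (floor semantics)."""

    def __init__(self, p: int) -> None:
        super().__init__()
        self.p = p

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if self.p == 1:
            self._in_len = x.shape[1]
            return x
        B, L, C = x.shape
        Lp = L // self.p
        self._in_len = L
        return x[:, : Lp * self.p, :].reshape(B, Lp, self.p, C).mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.p == 1:
            return dy
        B, Lp, C = dy.shape
        dx = np.zeros((B, self._in_len, C), dtype=dy.dtype)
        dx[:, : Lp * self.p, :] = np.repeat(dy / self.p, self.p, axis=1)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._len = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, None, :] / self._len, self._len, axis=1)


class Dense(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        super().__init__()
        lim = np.sqrt(6.0 / (cin + cout))  # Glorot uniform
        self.params["W"] = rng.uniform(-lim, lim, size=(cin, cout)).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


class ECA(Layer):
    """Efficient channel attention gate.

    Global average pooling over positions, a bias-free 1-D convolution of
    size ``k`` across the channel axis, a sigmoid, then a per-channel
    multiplicative gate on the input. Output shape equals input shape and
    gates lie in (0, 1).
    """

    def __init__(self, channels: int, k: int, rng: np.random.Generator) -> None:
        super().__init__()
        if k < 1 or k % 2 == 0:
            raise ValueError(f"ECA kernel size must be odd and >= 1, got {k}")
        self.channels, self.k = channels, k
        std = np.sqrt(1.0 / k)
        self.params["w"] = rng.normal(0.0, std, size=(k,)).astype(np.float32)

    def _channel_conv(self, s: np.ndarray) -> np.ndarray:
        half = self.k // 2
        sp = np.pad(s, ((0, 0), (half, half)))
        cols = sliding_window_view(sp, self.k, axis=1)  # (B, C, k)
        self._cols = cols
        return cols @ self.params["w"]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        self._L = x.shape[1]
        s = x.mean(axis=1)  # (B, C) channel descriptors
        t = self._channel_conv(s)
        g = 1.0 / (1.0 + np.exp(-t))
        self._g = g
        return x * g[:, None, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        g = self._g
        dx = dy * g[:, None, :]
        dg = (dy * self._x).sum(axis=1)  # (B, C)
        dt = dg * g * (1.0 - g)
        self.grads["w"] += np.einsum("bck,bc->k", self._cols, dt)
        half = self.k // 2
        B, C = dt.shape
        dsp = np.zeros((B, C + 2 * half), dtype=dy.dtype)
        w = self.params["w"]
        for j in range(self.k):
            dsp[:, j : j + C] += dt * w[j]
        ds = dsp[:, half : half + C]
        dx += ds[:, None, :] / self._L
        return dx

    @property
    def gates(self) -> np.ndarray:
        """Gates from the most recent forward pass."""
        return self._g


class Sequential(Layer):
    def __init__(self, children: list[Layer]) -> None:
        super().__init__()
        self.children = children

    def layers(self):
        for child in self.children:
            yield from child.layers()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for child in self.children:
            x = child.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for child in reversed(self.children):
            dy = child.backward(dy)
        return dy


class Residual(Layer):
    """``y = residual(x) + shortcut(x)``; the gradient splits across both
    branches and recombines at the input."""

    def __init__(self, residual: Layer, shortcut: Layer | None = None) -> None:
        super().__init__()
        self.residual = residual
        self.shortcut = shortcut  # None means identity

    def layers(self):
        yield from self.residual.layers()
        if self.shortcut is not None:
            yield from self.shortcut.layers()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        r = self.residual.forward(x, training)
        s = x if self.shortcut is None else self.shortcut.forward(x, training)
        if r.shape != s.shape:
            raise ValueError(
                f"residual/shortcut shape mismatch: {r.shape} vs {s.shape}"
            )
        return r + s

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dr = self.residual.backward(dy)
        ds = dy if self.shortcut is None else self.shortcut.backward(dy)
        return dr + ds
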