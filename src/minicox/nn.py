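"""Minimal trainable neural-network layers on numpy with manual backprop.

Layers store their inputs during ``forward`` and implement ``backward`` to
propagate an upstream gradient, accumulating parameter gradients in place.
This is enough to train the small 2D convolutional scoring networks used in
the simulation experiments; the survival losses supply the gradient of the
loss with respect to the network's scalar outputs.

Conventions: images are channels-last ``(N, H, W, C)``; convolutions are
stride 1 with "same" or "valid" padding; pooling does all downsampling.
Weights use fan-in-scaled (He) normal initialisation from a caller-provided
seeded generator.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Dense",
    "Conv2d",
    "MaxPool2d",
    "ReLU",
    "Flatten",
    "Sequential",
    "SGD",
]


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self) -> list:
        return []


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float64) -> None:
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = np.ascontiguousarray(x, dtype=self.W.dtype)
        return self._x @ self.W + self.b

    def backward(self, grad):
        grad = np.ascontiguousarray(grad, dtype=self.W.dtype)
        self.dW += self._x.T @ grad
        self.db += grad.sum(axis=0)
        return grad @ self.W.T

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Conv2d(Layer):
    """Stride-1 2D convolution via im2col, channels-last."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel_size: int,
        rng: np.random.Generator,
        padding: str = "same",
        dtype=np.float64,
    ) -> None:
        if padding not in ("same", "valid"):
            raise ValueError("padding must be 'same' or 'valid'")
        k = kernel_size
        fan_in = k * k * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, c_in, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k = k
        self.padding = padding
        self.c_in, self.c_out = c_in, c_out

    def _pad(self) -> int:
        return (self.k - 1) // 2 if self.padding == "same" else 0

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=self.W.dtype)
        n, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        p = self._pad()
        if p:
            x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xp_shape = x.shape
        # (N, Ho, Wo, k, k, C) view -> (N*Ho*Wo, k*k*C)
        win = sliding_window_view(x, (self.k, self.k), axis=(1, 2))
        win = win.transpose(0, 1, 2, 4, 5, 3)
        self._out_hw = win.shape[1:3]
        cols = win.reshape(-1, self.k * self.k * self.c_in)
        self._cols = cols
        # cols layout is (k, k, C) flattened, matching W.reshape
        wmat = self.W.reshape(self.k * self.k * self.c_in, self.c_out)
        out = cols @ wmat + self.b
        ho, wo = self._out_hw
        return out.reshape(n, ho, wo, self.c_out)

    def backward(self, grad):
        n, ho, wo, _ = grad.shape
        g = np.ascontiguousarray(grad, dtype=self.W.dtype).reshape(-1, self.c_out)
        wmat = self.W.reshape(-1, self.c_out)
        self.dW += (self._cols.T @ g).reshape(self.W.shape)
        self.db += g.sum(axis=0)
        dcols = (g @ wmat.T).reshape(n, ho, wo, self.k, self.k, self.c_in)
        dxp = np.zeros(self._xp_shape, dtype=self.W.dtype)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i : i + ho, j : j + wo, :] += dcols[:, :, :, i, j, :]
        p = self._pad()
        if p:
            dxp = dxp[:, p:-p, p:-p, :]
        return dxp

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]


class MaxPool2d(Layer):
    """2×2 max pooling with stride 2 (inputs must have even spatial dims)."""

    def forward(self, x):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2d expects even spatial dimensions")
        win = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        win = win.reshape(n, h // 2, w // 2, c, 4)
        self._argmax = win.argmax(axis=-1)
        self._in_shape = x.shape
        return win.max(axis=-1)

    def backward(self, grad):
        n, ho, wo, c = grad.shape
        dwin = np.zeros((n, ho, wo, c, 4))
        np.put_along_axis(dwin, self._argmax[..., None], grad[..., None], axis=-1)
        dwin = dwin.reshape(n, ho, wo, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dwin.reshape(self._in_shape)


class ReLU(Layer):
    """Rectifier with an optional small leak to avoid irreversibly dead
    units under large coordinated (full-batch) updates."""

    def __init__(self, slope: float = 0.0) -> None:
        self.slope = slope

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def zero_grad(self) -> None:
        for _, g in self.parameters():
            g[...] = 0.0

    # -- checkpointing --------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p for p, _ in self.parameters()]

    def save(self, path) -> None:
        np.savez(path, *[p for p, _ in self.parameters()])

    def load(self, path) -> None:
        with np.load(path) as data:
            arrays = [data[k] for k in data.files]
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint does not match architecture")
        for (p, _), a in zip(params, arrays):
            p[...] = a


class SGD:
    """Stochastic gradient descent with classical momentum.

    ``clip_norm`` rescales the global gradient norm when it exceeds the
    bound, which keeps losses with exponential terms (the full likelihood)
    from overshooting on small batches.
    """

    def __init__(self, params: list, lr: float, momentum: float = 0.9,
                 clip_norm: float | None = None) -> None:
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.clip_norm = clip_norm
        self.velocity = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        scale = 1.0
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for _, g in self.params))
            if total > self.clip_norm:
                scale = self.clip_norm / total
        for v, (p, g) in zip(self.velocity, self.params):
            v *= self.momentum
            v -= self.lr * scale * g
            p += v

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0
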