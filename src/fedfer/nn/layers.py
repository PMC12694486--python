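"""Minimal NumPy layers with exact forward/backward passes.

Data layout is channels-last: images are ``(N, H, W, C)`` float32. Convolutions
are 3x3, stride 1, valid (no padding); pooling is 2x2 max with stride 2 and
floor on odd extents. These choices pin down the parameter count and flatten
length of the architecture family exactly.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: forward caches what backward needs; backward returns dL/dx
    and stores parameter gradients on the layer."""

    name: str

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 valid convolution with bias, via im2col matmul."""

    def __init__(self, c_in: int, c_out: int, name: str):
        self.name = name
        self.c_in, self.c_out = c_in, c_out
        self.W = np.zeros((3, 3, c_in, c_out), dtype=np.float32)
        self.b = np.zeros((c_out,), dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self):
        return {f"{self.name}/W": self.W, f"{self.name}/b": self.b}

    def grads(self):
        return {f"{self.name}/W": self.dW, f"{self.name}/b": self.db}

    def forward(self, x, training=False, rng=None):
        n, h, w, c = x.shape
        oh, ow = h - 2, w - 2
        # (N, OH, OW, C, 3, 3) -> (N, OH, OW, 3, 3, C), flattened to match
        # W.reshape(9*C, c_out) whose leading index order is (kh, kw, c_in)
        win = sliding_window_view(x, (3, 3), axis=(1, 2))
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * oh * ow, 9 * c
        )
        out = cols @ self.W.reshape(9 * c, self.c_out) + self.b
        self._cols, self._xshape = cols, x.shape
        return out.reshape(n, oh, ow, self.c_out)

    def backward(self, dout):
        n, oh, ow, _ = dout.shape
        _, h, w, c = self._xshape
        d2 = dout.reshape(n * oh * ow, self.c_out)
        self.dW = (self._cols.T @ d2).reshape(self.W.shape)
        self.db = d2.sum(axis=0)
        dcols = (d2 @ self.W.reshape(9 * c, self.c_out).T).reshape(
            n, oh, ow, 3, 3, c
        )
        dx = np.zeros(self._xshape, dtype=dout.dtype)
        for i in range(3):
            for j in range(3):
                dx[:, i:i + oh, j:j + ow, :] += dcols[:, :, :, i, j, :]
        return dx


class ReLU(Layer):
    def __init__(self, name: str):
        self.name = name
        self._mask: np.ndarray | None = None

    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0)


class MaxPool2D(Layer):
    """2x2 max pool, stride 2; odd trailing rows/columns are dropped (floor)."""

    def __init__(self, name: str):
        self.name = name
        self._argmax: np.ndarray | None = None
        self._xshape: tuple | None = None

    def forward(self, x, training=False, rng=None):
        n, h, w, c = x.shape
        oh, ow = h // 2, w // 2
        xc = x[:, : oh * 2, : ow * 2, :]
        win = xc.reshape(n, oh, 2, ow, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(
            n, oh, ow, c, 4
        )
        self._argmax = win.argmax(axis=4)  # first max wins on ties
        self._xshape = x.shape
        return np.take_along_axis(win, self._argmax[..., None], axis=4)[..., 0]

    def backward(self, dout):
        n, h, w, c = self._xshape
        oh, ow = h // 2, w // 2
        dwin = np.zeros((n, oh, ow, c, 4), dtype=dout.dtype)
        np.put_along_axis(dwin, self._argmax[..., None], dout[..., None], axis=4)
        dx = np.zeros(self._xshape, dtype=dout.dtype)
        dx[:, : oh * 2, : ow * 2, :] = (
            dwin.reshape(n, oh, ow, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, oh * 2, ow * 2, c)
        )
        return dx


class Flatten(Layer):
    def __init__(self, name: str):
        self.name = name
        self._xshape: tuple | None = None

    def forward(self, x, training=False, rng=None):
        self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._xshape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, name: str):
        self.name = name
        self.n_in, self.n_out = n_in, n_out
        self.W = np.zeros((n_in, n_out), dtype=np.float32)
        self.b = np.zeros((n_out,), dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return {f"{self.name}/W": self.W, f"{self.name}/b": self.b}

    def grads(self):
        return {f"{self.name}/W": self.dW, f"{self.name}/b": self.db}

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T


class Dropout(Layer):
    """Inverted dropout: active only in training mode, identity at inference."""

    def __init__(self, rate: float, name: str):
        self.name = name
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        keep = np.float32(1.0 - self.rate)
        self._mask = (rng.random(x.shape) >= self.rate).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
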