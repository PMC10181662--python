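"""Minimal NumPy neural-network core shared by the seed and pixel classifiers.

Implements exactly the pieces the two architectures need — valid (unpadded)
3-D convolution, 3-D max pooling with replication-equivalent edge handling,
dense layers, ReLU, softmax cross-entropy, and Adam — with explicit
backward passes.  Convolutions are vectorised with
``sliding_window_view`` + ``tensordot`` so CPU training of the small
default networks stays fast; everything is deterministic for a fixed
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv3d_batch",
    "Conv3dLayer",
    "MaxPool3dLayer",
    "DenseLayer",
    "ReluLayer",
    "FlattenLayer",
    "Sequential",
    "Adam",
    "softmax",
    "cross_entropy_and_grad",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilised."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_and_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(y)
    eps = 1e-12
    loss = -float(np.mean(np.log(p[np.arange(n), y] + eps)))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


def conv3d_batch(x: np.ndarray, kernel: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Valid 3-D convolution of a batch.

    x: (N, C, D, H, W); kernel: (C', C, D', H', W'); bias: (C',).
    Output: (N, C', D-D'+1, H-H'+1, W-W'+1).
    """
    _, _, kd, kh, kw = kernel.shape
    if kd > x.shape[2] or kh > x.shape[3] or kw > x.shape[4]:
        raise ValueError(
            f"kernel spatial size {(kd, kh, kw)} exceeds input {x.shape[2:]}"
        )
    # windows: (N, C, Do, Ho, Wo, D', H', W')
    win = sliding_window_view(x, (kd, kh, kw), axis=(2, 3, 4))
    out = np.tensordot(win, kernel, axes=([1, 5, 6, 7], [1, 2, 3, 4]))
    out = np.moveaxis(out, -1, 1)  # (N, C', Do, Ho, Wo)
    return out + bias[None, :, None, None, None]


class Conv3dLayer:
    """Trainable valid 3-D convolution with He-style init."""

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int, int],
                 rng: np.random.Generator):
        kd, kh, kw = kernel
        fan_in = in_ch * kd * kh * kw
        scale = np.sqrt(2.0 / fan_in)
        self.W = rng.normal(0.0, scale, size=(out_ch, in_ch, kd, kh, kw))
        self.b = np.zeros(out_ch)
        self._win: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        kd, kh, kw = self.W.shape[2:]
        if kd > x.shape[2] or kh > x.shape[3] or kw > x.shape[4]:
            raise ValueError(
                f"kernel spatial size {(kd, kh, kw)} exceeds input {x.shape[2:]}"
            )
        win = sliding_window_view(x, (kd, kh, kw), axis=(2, 3, 4))
        if train:
            self._win = win
            self._xshape = x.shape
        out = np.tensordot(win, self.W, axes=([1, 5, 6, 7], [1, 2, 3, 4]))
        return np.moveaxis(out, -1, 1) + self.b[None, :, None, None, None]

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        assert self._win is not None and self._xshape is not None
        # dW[co, c, dk, hk, wk] = sum_{n, do, ho, wo} win[n, c, do, ho, wo, dk, hk, wk] * dout[n, co, do, ho, wo]
        dW = np.tensordot(dout, self._win, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
        db = dout.sum(axis=(0, 2, 3, 4))
        # dx: full correlation of dout with the spatially flipped kernel.
        kd, kh, kw = self.W.shape[2:]
        pad = [(0, 0), (0, 0), (kd - 1, kd - 1), (kh - 1, kh - 1), (kw - 1, kw - 1)]
        dpad = np.pad(dout, pad)
        dwin = sliding_window_view(dpad, (kd, kh, kw), axis=(2, 3, 4))
        Wflip = self.W[:, :, ::-1, ::-1, ::-1]
        dx = np.tensordot(dwin, Wflip, axes=([1, 5, 6, 7], [0, 2, 3, 4]))
        dx = np.moveaxis(dx, -1, 1)
        self._win = None
        return dx, [dW, db]


class MaxPool3dLayer:
    """Max pooling with stride = window.

    When a dimension is not divisible by the pool size the input is edge-
    padded by replication before pooling (implemented by -inf padding,
    which yields identical window maxima since replicated values duplicate
    in-window edge cells).
    """

    params: list[np.ndarray] = []

    def __init__(self, pool: tuple[int, int, int]):
        self.pool = pool
        self._cache = None

    def _padded(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, int, int]]:
        pd, ph, pw = self.pool
        n, c, d, h, w = x.shape
        dd, dh, dw = (-d) % pd, (-h) % ph, (-w) % pw
        if dd or dh or dw:
            x = np.pad(x, [(0, 0), (0, 0), (0, dd), (0, dh), (0, dw)],
                       constant_values=-np.inf)
        return x, (d, h, w)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        pd, ph, pw = self.pool
        xp, orig = self._padded(x)
        n, c, d, h, w = xp.shape
        win = xp.reshape(n, c, d // pd, pd, h // ph, ph, w // pw, pw)
        win = win.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            n, c, d // pd, h // ph, w // pw, pd * ph * pw
        )
        if train:
            arg = win.argmax(axis=-1)
            self._cache = (arg, xp.shape, orig)
        return win.max(axis=-1)

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        assert self._cache is not None
        arg, pshape, (d, h, w) = self._cache
        pd, ph, pw = self.pool
        n, c = pshape[0], pshape[1]
        do, ho, wo = pshape[2] // pd, pshape[3] // ph, pshape[4] // pw
        flat = np.zeros((n, c, do, ho, wo, pd * ph * pw))
        np.put_along_axis(flat, arg[..., None], dout[..., None], axis=-1)
        dx = flat.reshape(n, c, do, ho, wo, pd, ph, pw).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        dx = dx.reshape(n, c, pshape[2], pshape[3], pshape[4])[:, :, :d, :h, :w]
        self._cache = None
        return dx, []


class ReluLayer:
    params: list[np.ndarray] = []

    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        dx = dout * self._mask
        self._mask = None
        return dx, []


class FlattenLayer:
    params: list[np.ndarray] = []

    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        return dout.reshape(self._shape), []


class DenseLayer:
    """Affine layer ``x @ W + b`` with He-style init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self._x = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[-1] != self.W.shape[0]:
            raise ValueError(f"input width {x.shape[-1]} != layer fan-in {self.W.shape[0]}")
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        dW = self._x.T @ dout
        db = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx, [dW, db]


class Sequential:
    """Plain layer stack with joint forward/backward."""

    def __init__(self, layers: list):
        self.layers = layers

    @property
    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> list[np.ndarray]:
        grads: list[np.ndarray] = []
        for layer in reversed(self.layers):
            dout, g = layer.backward(dout)
            grads = g + grads
        return grads


class Adam:
    """Adam optimiser updating parameter arrays in place."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        if len(grads) != len(self.params):
            raise ValueError("gradient count does not match parameter count")
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
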