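"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for a small convolutional encoder-decoder: tensors
with tape-based backward, im2col 3x3 convolution, 1x1 convolution, 2x2 max
pooling, bilinear x2 upsampling, channel concatenation, ReLU, sigmoid and
mean-squared-error.  Layout is NCHW throughout.  All parameters live in
:class:`Parameter` tensors and are updated by :class:`Adam`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "conv2d", "conv1x1", "maxpool2", "upsample2",
           "concat", "relu", "sigmoid", "hardsigmoid", "add", "mse", "Adam"]


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()

        def topo(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                topo(p)
            order.append(t)

        topo(self)
        for t in order:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None:
                t._backward(t.grad)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _accum(t: Tensor, g):
    if t.requires_grad and t.grad is not None:
        t.grad += g


def conv2d(x: Tensor, w: Parameter, b: Parameter) -> Tensor:
    """3x3 same-padding convolution, NCHW; w is (Cout, Cin, 3, 3)."""
    N, C, H, W = x.data.shape
    Co = w.data.shape[0]
    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # cols: (N, C, H, W, 3, 3) -> (N*H*W, C*9)
    cols_m = cols.transpose(0, 2, 3, 1, 4, 5).reshape(N * H * W, C * 9)
    wm = w.data.reshape(Co, C * 9)
    y = (cols_m @ wm.T + b.data).reshape(N, H, W, Co).transpose(0, 3, 1, 2)

    def backward(gy):
        gym = gy.transpose(0, 2, 3, 1).reshape(N * H * W, Co)
        _accum(w, (gym.T @ cols_m).reshape(w.data.shape))
        _accum(b, gym.sum(axis=0))
        if x.requires_grad:
            gcols = (gym @ wm).reshape(N, H, W, C, 3, 3)
            gxp = np.zeros_like(xp)
            for di in range(3):
                for dj in range(3):
                    gxp[:, :, di : di + H, dj : dj + W] += gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
            _accum(x, gxp[:, :, 1 : 1 + H, 1 : 1 + W])

    return Tensor(y, (x, w, b), backward)


def conv1x1(x: Tensor, w: Parameter, b: Parameter) -> Tensor:
    """Pointwise convolution; w is (Cout, Cin)."""
    y = np.einsum("oc,nchw->nohw", w.data, x.data) + b.data[None, :, None, None]

    def backward(gy):
        _accum(w, np.einsum("nohw,nchw->oc", gy, x.data))
        _accum(b, gy.sum(axis=(0, 2, 3)))
        _accum(x, np.einsum("oc,nohw->nchw", w.data, gy))

    return Tensor(y, (x, w, b), backward)


def maxpool2(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    xr = x.data.reshape(N, C, H // 2, 2, W // 2, 2)
    y = xr.max(axis=(3, 5))

    def backward(gy):
        mask = xr == y[:, :, :, None, :, None]
        counts = mask.sum(axis=(3, 5), keepdims=True)
        g = mask * (gy[:, :, :, None, :, None] / counts)
        _accum(x, g.reshape(N, C, H, W))

    return Tensor(y, (x,), backward)


def _linear_weights(n_out: int, n_in: int):
    """Index/weight pairs for x2 bilinear upsampling (half-pixel centres)."""
    pos = (np.arange(n_out) + 0.5) / 2.0 - 0.5
    i0 = np.clip(np.floor(pos).astype(int), 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    w1 = np.clip(pos - np.floor(pos), 0.0, 1.0)
    w1[pos < 0] = 0.0
    w1[pos > n_in - 1] = 0.0
    return i0, i1, 1.0 - w1, w1


def upsample2(x: Tensor) -> Tensor:
    """Bilinear x2 upsampling (half-pixel alignment), separable."""
    N, C, H, W = x.data.shape
    i0, i1, a0, a1 = _linear_weights(2 * H, H)
    j0, j1, b0, b1 = _linear_weights(2 * W, W)
    yh = a0[:, None] * x.data[:, :, i0, :] + a1[:, None] * x.data[:, :, i1, :]
    y = b0 * yh[:, :, :, j0] + b1 * yh[:, :, :, j1]

    def backward(gy):
        gh = np.zeros((N, C, 2 * H, W))
        np.add.at(gh, (slice(None), slice(None), slice(None), j0), (b0 * gy)[..., :])
        np.add.at(gh, (slice(None), slice(None), slice(None), j1), (b1 * gy)[..., :])
        gx = np.zeros((N, C, H, W))
        np.add.at(gx, (slice(None), slice(None), i0, slice(None)), a0[:, None] * gh)
        np.add.at(gx, (slice(None), slice(None), i1, slice(None)), a1[:, None] * gh)
        _accum(x, gx)

    return Tensor(y, (x,), backward)


def concat(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]
    y = np.concatenate([a.data, b.data], axis=1)

    def backward(gy):
        _accum(a, gy[:, :ca])
        _accum(b, gy[:, ca:])

    return Tensor(y, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, 0.0)

    def backward(gy):
        _accum(x, gy * (x.data > 0))

    return Tensor(y, (x,), backward)


def hardsigmoid(x: Tensor) -> Tensor:
    """Bounded linear activation clip(x, 0, 1) with a small leak outside.

    Unit gradient across the whole displayable range avoids the saturation
    stall a logistic head suffers on near-binary targets; the 0.01 leak
    keeps clipped units trainable.
    """
    y = np.clip(x.data, 0.0, 1.0)

    def backward(gy):
        inside = (x.data > 0.0) & (x.data < 1.0)
        _accum(x, gy * np.where(inside, 1.0, 0.01))

    return Tensor(y, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))

    def backward(gy):
        _accum(x, gy * y * (1.0 - y))

    return Tensor(y, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    y = a.data + b.data

    def backward(gy):
        _accum(a, gy)
        _accum(b, gy)

    return Tensor(y, (a, b), backward)


def mse(pred: Tensor, label: np.ndarray) -> Tensor:
    diff = pred.data - label
    y = np.array(np.mean(diff**2))

    def backward(gy):
        _accum(pred, gy * 2.0 * diff / diff.size)

    return Tensor(y, (pred,), backward)


class Adam:
    """Adaptive-moment optimizer over a list of Parameters."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
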