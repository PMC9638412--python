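"""A compact reverse-mode autodiff engine on numpy arrays.

Supports exactly the operations the multi-resolution segmentation network
needs: strided 2-D convolution, batch normalization, ReLU, sigmoid, residual
addition, channel concatenation, bilinear upsampling and mean-squared-error
loss, plus an Adam optimizer.  Tensors are NCHW float64; gradients are exact
(convolution backward is expressed as a transposed convolution so everything
stays on the matmul fast path) and are verified against finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .._interp import interp_matrix

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(self, data, requires_grad=False, parents=(), backward_fn=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.parents = parents
        self.backward_fn = backward_fn
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        """Reverse-mode sweep from this (scalar) tensor."""
        order = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node.backward_fn is not None and node.grad is not None:
                node.backward_fn(node.grad)

    def zero_grad(self):
        self.grad = None


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad += g


def _node(data, parents, backward_fn):
    if _GRAD_ENABLED and any(p.requires_grad or p.parents for p in parents):
        return Tensor(data, parents=parents, backward_fn=backward_fn, requires_grad=True)
    return Tensor(data)


# ---------------------------------------------------------------------------
# convolution


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return cols, ho, wo


def _conv_raw(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> np.ndarray:
    cout, _cin, kh, kw = w.shape
    cols, ho, wo = _im2col(x, kh, kw, stride, pad)
    y = cols @ w.reshape(cout, -1).T
    return y.reshape(x.shape[0], ho, wo, cout).transpose(0, 3, 1, 2)


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int | None = None) -> Tensor:
    """2-D convolution (cross-correlation), zero padding, square stride."""
    cout, cin, kh, kw = w.shape
    if pad is None:
        pad = kh // 2
    y = _conv_raw(x.data, w.data, stride, pad) + b.data[None, :, None, None]
    n, _, hin, win_ = x.data.shape
    _, _, ho, wo = y.shape

    def backward_fn(g):
        gcols = g.transpose(0, 2, 3, 1).reshape(-1, cout)
        if w.requires_grad:
            cols, _, _ = _im2col(x.data, kh, kw, stride, pad)
            _accum(w, (gcols.T @ cols).reshape(w.shape))
        if b.requires_grad:
            _accum(b, gcols.sum(axis=0))
        if x.requires_grad or x.parents:
            # transposed convolution: dilate the gradient by the stride,
            # full-pad, and correlate with the spatially flipped kernel
            ld_h, ld_w = (ho - 1) * stride + 1, (wo - 1) * stride + 1
            gd = np.zeros((n, cout, ld_h + 2 * (kh - 1), ld_w + 2 * (kw - 1)))
            gd[:, :, kh - 1 : kh - 1 + ld_h : stride, kw - 1 : kw - 1 + ld_w : stride] = g
            wf = w.data.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
            part = _conv_raw(gd, wf, 1, 0)  # (n, cin, ld_h + kh - 1, ld_w + kw - 1)
            hp, wp = hin + 2 * pad, win_ + 2 * pad
            dxp = np.zeros((n, cin, hp, wp))
            dxp[:, :, : part.shape[2], : part.shape[3]] = part
            _accum(x, dxp[:, :, pad : pad + hin, pad : pad + win_])

    return _node(y, (x, w, b), backward_fn)


# ---------------------------------------------------------------------------
# batch normalization


class BatchNormState:
    """Running statistics of one BN layer (per channel)."""

    def __init__(self, channels: int):
        self.mean = np.zeros(channels)
        self.var = np.ones(channels)


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    state: BatchNormState,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    axes = (0, 2, 3)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        state.mean = (1 - momentum) * state.mean + momentum * mean
        state.var = (1 - momentum) * state.var + momentum * var
    else:
        mean, var = state.mean, state.var
    istd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * istd[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def backward_fn(g):
        if gamma.requires_grad:
            _accum(gamma, (g * xhat).sum(axis=axes))
        if beta.requires_grad:
            _accum(beta, g.sum(axis=axes))
        if x.requires_grad or x.parents:
            gxhat = g * gamma.data[None, :, None, None]
            if training:
                s1 = gxhat.sum(axis=axes)[None, :, None, None]
                s2 = (gxhat * xhat).sum(axis=axes)[None, :, None, None]
                dx = (istd[None, :, None, None] / m) * (m * gxhat - s1 - xhat * s2)
            else:
                dx = gxhat * istd[None, :, None, None]
            _accum(x, dx)

    return _node(y, (x, gamma, beta), backward_fn)


# ---------------------------------------------------------------------------
# pointwise / structural ops


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward_fn(g):
        _accum(x, g * mask)

    return _node(x.data * mask, (x,), backward_fn)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))

    def backward_fn(g):
        _accum(x, g * y * (1.0 - y))

    return _node(y, (x,), backward_fn)


def add(x: Tensor, y: Tensor) -> Tensor:
    def backward_fn(g):
        _accum(x, g)
        _accum(y, g)

    return _node(x.data + y.data, (x, y), backward_fn)


def concat(tensors: list[Tensor]) -> Tensor:
    sizes = [t.data.shape[1] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward_fn(g):
        for t, o0, o1 in zip(tensors, offsets[:-1], offsets[1:]):
            _accum(t, g[:, o0:o1])

    return _node(np.concatenate([t.data for t in tensors], axis=1), tuple(tensors), backward_fn)


def upsample_bilinear(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resize of the spatial axes; the adjoint is the transpose of
    the interpolation matrices."""
    h_in, w_in = x.data.shape[2:]
    mr = interp_matrix(h_in, out_hw[0])
    mc = interp_matrix(w_in, out_hw[1])
    y = np.einsum("ij,ncjk,lk->ncil", mr, x.data, mc, optimize=True)

    def backward_fn(g):
        _accum(x, np.einsum("ji,ncjk,kl->ncil", mr, g, mc, optimize=True))

    return _node(y, (x,), backward_fn)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred.data - target
    n = diff.size

    def backward_fn(g):
        _accum(pred, g * 2.0 * diff / n)

    return _node(np.mean(diff**2), (pred,), backward_fn)


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam with bias correction; operates on a dict of parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None
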