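"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the primitives needed by the trainable layers in this
package (dense/convolutional layers, unrolled FISTA, wavelet filter banks,
the Gaussian-mixture loss): elementwise arithmetic with broadcasting,
matmul, the standard activations, reductions, shape ops, 2D convolution
with stride, pooling/upsampling and zero-dilation for transposed
convolution.

Gradients are accumulated by a topological-order backward pass over the
recorded graph (``Tensor.backward``).  All ops accept plain numbers /
ndarrays and lift them to constant tensors.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "conv2d", "avg_pool2d", "upsample_nearest",
           "dilate2d", "pad2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (gs, ss) in enumerate(zip(grad.shape, shape)):
        if ss == 1 and gs != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=float), requires_grad=False)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=float)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if not self.requires_grad:
            return
        g = _unbroadcast(np.asarray(g, dtype=float), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        o = _as_tensor(other)

        def bw(g):
            self._accum(g)
            o._accum(g)

        return self._make(self.data + o.data, (self, o), bw)

    __radd__ = __add__

    def __mul__(self, other):
        o = _as_tensor(other)

        def bw(g):
            self._accum(g * o.data)
            o._accum(g * self.data)

        return self._make(self.data * o.data, (self, o), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        o = _as_tensor(other)

        def bw(g):
            self._accum(g / o.data)
            o._accum(-g * self.data / (o.data ** 2))

        return self._make(self.data / o.data, (self, o), bw)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, k):
        k = float(k)

        def bw(g):
            self._accum(g * k * self.data ** (k - 1.0))

        return self._make(self.data ** k, (self,), bw)

    def __matmul__(self, other):
        o = _as_tensor(other)

        def bw(g):
            a, b = self.data, o.data
            if a.ndim == 1 and b.ndim == 1:
                self._accum(g * b)
                o._accum(g * a)
            elif a.ndim == 1:
                self._accum(g @ b.T)
                o._accum(np.outer(a, g))
            elif b.ndim == 1:
                self._accum(np.outer(g, b))
                o._accum(a.T @ g)
            else:
                self._accum(g @ np.swapaxes(b, -1, -2))
                o._accum(_unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape))

        return self._make(self.data @ o.data, (self, o), bw)

    # -- elementwise functions --------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accum(g * 0.5 / out_data)

        return self._make(out_data, (self,), bw)

    def abs(self):
        def bw(g):
            self._accum(g * np.sign(self.data))

        return self._make(np.abs(self.data), (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def bw(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), bw)

    def softplus(self):
        # numerically stable log(1+exp(x))
        out_data = np.logaddexp(0.0, self.data)

        def bw(g):
            self._accum(g / (1.0 + np.exp(-self.data)))

        return self._make(out_data, (self,), bw)

    # -- reductions & shape ops -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(g):
            self._accum(g.reshape(self.data.shape))

        return self._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx):
        def bw(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            self._accum(acc)

        return self._make(self.data[idx], (self,), bw)

    def detach(self):
        return Tensor(self.data.copy(), requires_grad=False)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


# -- free functions --------------------------------------------------------

def concat(tensors, axis=0):
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=(1, 1), padding=(0, 0)) -> Tensor:
    """2D cross-correlation: x [N,C,H,W], w [O,C,kh,kw] -> [N,O,Ho,Wo]."""
    x, w = _as_tensor(x), _as_tensor(w)
    sh, sw = (stride, stride) if np.isscalar(stride) else stride
    ph, pw = (padding, padding) if np.isscalar(padding) else padding
    kh, kw = w.data.shape[2:]
    n_out, c_in = w.data.shape[:2]
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    nb, _, Ho, Wo = win.shape[:4]
    # im2col: one contiguous copy, then plain BLAS matmuls in both passes
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        nb * Ho * Wo, c_in * kh * kw)
    w2 = w.data.reshape(n_out, -1)
    out_data = (cols @ w2.T).reshape(nb, Ho, Wo, n_out).transpose(0, 3, 1, 2)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def bw(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(
            nb * Ho * Wo, n_out)
        if w.requires_grad:
            w._accum((g2.T @ cols).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g2.sum(axis=0))
        if x.requires_grad:
            gcols = (g2 @ w2).reshape(nb, Ho, Wo, c_in, kh, kw)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + sh * Ho:sh, j:j + sw * Wo:sw] += \
                        gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if ph or pw:
                gxp = gxp[:, :, ph:gxp.shape[2] - ph, pw:gxp.shape[3] - pw]
            x._accum(gxp)

    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = bw
    return out


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    assert h % k == 0 and w % k == 0, "pooling factor must divide spatial dims"
    out_data = x.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def bw(g):
        x._accum(np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k))

    return x._make(out_data, (x,), bw)


def upsample_nearest(x: Tensor, k: int) -> Tensor:
    x = _as_tensor(x)
    out_data = np.repeat(np.repeat(x.data, k, axis=2), k, axis=3)

    def bw(g):
        n, c, h, w = x.data.shape
        x._accum(g.reshape(n, c, h, k, w, k).sum(axis=(3, 5)))

    return x._make(out_data, (x,), bw)


def pad2d(x: Tensor, pads) -> Tensor:
    """Zero-pad the two trailing (spatial) axes; pads = ((top,bottom),(left,right))."""
    x = _as_tensor(x)
    (t, b), (l, r) = pads
    widths = [(0, 0)] * (x.data.ndim - 2) + [(t, b), (l, r)]
    out_data = np.pad(x.data, widths)

    def bw(g):
        sl = [slice(None)] * (x.data.ndim - 2)
        sl += [slice(t, g.shape[-2] - b), slice(l, g.shape[-1] - r)]
        x._accum(g[tuple(sl)])

    return x._make(out_data, (x,), bw)


def dilate2d(x: Tensor, k: int) -> Tensor:
    """Insert k-1 zeros between spatial samples (transposed-conv upsampling)."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    out_data = np.zeros((n, c, h * k, w * k), dtype=float)
    out_data[:, :, ::k, ::k] = x.data

    def bw(g):
        x._accum(g[:, :, ::k, ::k])

    return x._make(out_data, (x,), bw)
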