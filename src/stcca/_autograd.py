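"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Only the operations the network needs are implemented: broadcast-aware
arithmetic, (batched) matmul, valid 2-D convolution, average pooling,
batch/layer normalisation, ELU, softmax, dropout, reshape/transpose/concat,
and a fused softmax cross-entropy.  Gradients are accumulated into
``Tensor.grad`` by :meth:`Tensor.backward` in reverse topological order.

The engine is dtype-preserving: float32 inputs stay float32 throughout
(the network trains in float32 for speed), while float64 inputs give
float64 math for high-precision checks.  Scalar constants are applied
with :func:`scale`/:func:`shift` so they never promote the dtype.
Execution is deterministic: identical inputs produce bit-identical
outputs and gradients.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_FLOAT_TYPES = (np.float32, np.float64)


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_n_uses")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        arr = np.asarray(data)
        if arr.dtype not in _FLOAT_TYPES:
            arr = arr.astype(np.float64)
        self.data = arr
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward
        self._n_uses = 0

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g):
        if self.grad is None:
            # a tensor with a single consumer receives exactly one
            # contribution, so it may take ownership without copying
            self.grad = np.array(g) if self._n_uses > 1 else np.asarray(g)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar output")
            grad = np.ones_like(self.data)
        order, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        for t in order:
            t._n_uses = 0
        for t in order:
            for p in t._parents:
                p._n_uses += 1
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(order):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    # -- convenience arithmetic ------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __sub__(self, other):
        return add(self, scale(_as_tensor(other), -1.0))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def reshape(self, *shape):
        return reshape(self, shape)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


# -- primitive ops --------------------------------------------------------

def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    out._backward = backward
    return out


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    out._backward = backward
    return out


def scale(a, c):
    """Multiply by a python scalar without promoting the dtype."""
    a = _as_tensor(a)
    c = float(c)
    out = Tensor(a.data * np.asarray(c, dtype=a.data.dtype), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * np.asarray(c, dtype=g.dtype))

    out._backward = backward
    return out


def shift(a, c):
    """Add a python scalar without promoting the dtype."""
    a = _as_tensor(a)
    out = Tensor(a.data + np.asarray(float(c), dtype=a.data.dtype), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g)

    out._backward = backward
    return out


def matmul(a, b):
    """Batched matrix product with NumPy broadcasting on leading axes."""
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data @ b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.shape))

    out._backward = backward
    return out


def reshape(a, shape):
    a = _as_tensor(a)
    out = Tensor(a.data.reshape(shape), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.shape))

    out._backward = backward
    return out


def transpose(a, axes):
    a = _as_tensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    out = Tensor(a.data.transpose(axes), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.ascontiguousarray(g.transpose(inv)))

    out._backward = backward
    return out


def concat(tensors, axis=-1):
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(np.ascontiguousarray(p))

    out._backward = backward
    return out


def elu(a):
    """ELU with alpha = 1: x for x >= 0, exp(x) - 1 otherwise."""
    a = _as_tensor(a)
    pos = a.data >= 0
    y = np.where(pos, a.data, np.expm1(np.minimum(a.data, 0.0)))
    out = Tensor(y, parents=(a,))

    def backward(g):
        if a.requires_grad:
            one = np.asarray(1.0, dtype=y.dtype)
            a._accumulate(g * np.where(pos, one, y + one))

    out._backward = backward
    return out


def softmax(a, axis=-1):
    """Numerically stable softmax (max-subtraction) along ``axis``."""
    a = _as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    np.exp(z, out=z)
    z /= z.sum(axis=axis, keepdims=True)
    y = z
    out = Tensor(y, parents=(a,))

    def backward(g):
        if a.requires_grad:
            dot = np.einsum("...i,...i->...", g, y)[..., None]
            # g is this node's own grad buffer; it is not read again, so
            # the Jacobian product may be formed in place
            g -= dot
            g *= y
            a._accumulate(g)

    out._backward = backward
    return out


def mean(a, axis, keepdims=False):
    a = _as_tensor(a)
    out = Tensor(a.data.mean(axis=axis, keepdims=keepdims,
                             dtype=a.data.dtype), parents=(a,))
    axes = axis if isinstance(axis, tuple) else (axis,)
    n = np.prod([a.shape[ax] for ax in axes])

    def backward(g):
        if a.requires_grad:
            gg = g if keepdims else np.expand_dims(g, axes)
            a._accumulate(np.broadcast_to(gg / np.asarray(n, dtype=gg.dtype),
                                          a.shape).copy())

    out._backward = backward
    return out


def attention(Q, K, V, dk):
    """Fused scaled dot-product attention: softmax(Q·Kᵀ/√dk)·V.

    One graph node instead of five keeps the L × L score matrices out of
    the autodiff graph; the softmax Jacobian product is formed in place.
    """
    Q, K, V = _as_tensor(Q), _as_tensor(K), _as_tensor(V)
    inv = 1.0 / np.sqrt(dk)
    Qs = Q.data * np.asarray(inv, dtype=Q.data.dtype)
    P = Qs @ np.swapaxes(K.data, -1, -2)
    P -= P.max(axis=-1, keepdims=True)
    np.exp(P, out=P)
    P /= P.sum(axis=-1, keepdims=True)
    out = Tensor(P @ V.data, parents=(Q, K, V))

    def backward(dO):
        if V.requires_grad:
            V._accumulate(np.swapaxes(P, -1, -2) @ dO)
        if Q.requires_grad or K.requires_grad:
            dP = dO @ np.swapaxes(V.data, -1, -2)
            rowdot = np.einsum("...ij,...ij->...i", dP, P)[..., None]
            dP -= rowdot
            dP *= P  # dP is now dS, the score gradient
            if Q.requires_grad:
                dQ = dP @ K.data
                dQ *= np.asarray(inv, dtype=dQ.dtype)
                Q._accumulate(dQ)
            if K.requires_grad:
                K._accumulate(np.swapaxes(dP, -1, -2) @ Qs)

    out._backward = backward
    return out


def conv2d(x, w):
    """Valid cross-correlation, stride 1, no bias.

    x: (B, Cin, H, W); w: (Cout, Cin, kh, kw) -> (B, Cout, H-kh+1, W-kw+1).
    Lowered to BLAS matmuls via im2col (tensordot).
    """
    x, w = _as_tensor(x), _as_tensor(w)
    kh, kw = w.shape[2], w.shape[3]
    win = sliding_window_view(x.data, (kh, kw), axis=(2, 3))  # B,Cin,H',W',kh,kw
    y = np.tensordot(win, w.data, axes=((1, 4, 5), (1, 2, 3)))  # B,H',W',Cout
    out = Tensor(np.ascontiguousarray(np.moveaxis(y, -1, 1)), parents=(x, w))

    def backward(g):
        if w.requires_grad:
            dw = np.tensordot(g, win, axes=((0, 2, 3), (0, 2, 3)))  # Cout,Cin,kh,kw
            w._accumulate(dw)
        if x.requires_grad:
            gpad = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
            gwin = sliding_window_view(gpad, (kh, kw), axis=(2, 3))
            wflip = w.data[:, :, ::-1, ::-1]
            dx = np.tensordot(gwin, wflip, axes=((1, 4, 5), (0, 2, 3)))  # B,H,W,Cin
            x._accumulate(np.ascontiguousarray(np.moveaxis(dx, -1, 1)))

    out._backward = backward
    return out


def avg_pool2d(x, window):
    """Average pooling with stride equal to the window; remainder dropped."""
    x = _as_tensor(x)
    ph, pw = window
    B, C, H, W = x.shape
    oh, ow = H // ph, W // pw
    if oh < 1 or ow < 1:
        raise ValueError(
            f"avg_pool2d: input ({H}x{W}) smaller than window ({ph}x{pw})"
        )
    crop = x.data[:, :, : oh * ph, : ow * pw]
    y = crop.reshape(B, C, oh, ph, ow, pw).mean(axis=(3, 5), dtype=x.data.dtype)
    out = Tensor(y, parents=(x,))

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            inv = np.asarray(1.0 / (ph * pw), dtype=g.dtype)
            gexp = np.repeat(np.repeat(g * inv, ph, axis=2), pw, axis=3)
            gx[:, :, : oh * ph, : ow * pw] = gexp
            x._accumulate(gx)

    out._backward = backward
    return out


def dropout(x, p, rng, training):
    """Inverted dropout: active only in training mode."""
    x = _as_tensor(x)
    if not training or p <= 0.0:
        return x
    mask = ((rng.random(x.shape) >= p) / (1.0 - p)).astype(x.data.dtype)
    out = Tensor(x.data * mask, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    out._backward = backward
    return out


def cross_entropy(logits, labels):
    """Mean negative log-softmax probability of the true class.

    logits: (B, m); labels: int array of zero-based class indices.
    """
    logits = _as_tensor(logits)
    labels = np.asarray(labels, dtype=np.intp)
    B, m = logits.shape
    if labels.shape != (B,):
        raise ValueError("labels must be one class index per row of logits")
    if labels.min() < 0 or labels.max() >= m:
        raise ValueError(f"label out of range 0..{m - 1}")
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    loss = -logp[np.arange(B), labels].mean(dtype=np.float64)
    out = Tensor(loss, parents=(logits,))

    def backward(g):
        if logits.requires_grad:
            p = np.exp(logp)
            p[np.arange(B), labels] -= 1.0
            logits._accumulate(np.asarray(g, dtype=p.dtype) * p / B)

    out._backward = backward
    return out
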