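"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine records a computation graph of :class:`Tensor` nodes.  Every
primitive's vector-Jacobian product (VJP) is itself expressed with the
engine's primitives, so gradients are ordinary graph nodes and
higher-order derivatives (e.g. differentiating a gradient-norm penalty
with respect to network weights) come for free.

Only the operations needed by this package are provided: broadcasting
arithmetic, reductions, shape manipulation, gather/scatter, and a
stride-1 2-D convolution.  Data is kept in float64 throughout.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "astensor",
    "grad",
    "add",
    "mul",
    "matmul",
    "tsum",
    "tmax",
    "reshape",
    "transpose",
    "flip",
    "concatenate",
    "pad_constant",
    "broadcast_to",
    "gather",
    "scatter_add",
    "conv2d",
    "exp",
    "log",
    "sqrt",
    "tabs",
    "relu",
    "maximum",
    "sigmoid",
]


class Tensor:
    """A node in the computation graph wrapping a numpy array."""

    __slots__ = ("data", "parents", "vjp", "requires_grad")

    def __init__(
        self,
        data,
        parents: tuple = (),
        vjp: Callable | None = None,
        requires_grad: bool | None = None,
    ):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = parents
        self.vjp = vjp
        if requires_grad is None:
            requires_grad = any(p.requires_grad for p in parents)
        self.requires_grad = bool(requires_grad)

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data.reshape(()))

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, astensor(other))

    def __radd__(self, other):
        return add(astensor(other), self)

    def __sub__(self, other):
        return add(self, neg(astensor(other)))

    def __rsub__(self, other):
        return add(astensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, astensor(other))

    def __rmul__(self, other):
        return mul(astensor(other), self)

    def __truediv__(self, other):
        return mul(self, power(astensor(other), -1.0))

    def __rtruediv__(self, other):
        return mul(astensor(other), power(self, -1.0))

    def __neg__(self):
        return neg(self)

    def __pow__(self, k):
        return power(self, k)

    def __matmul__(self, other):
        return matmul(self, astensor(other))

    def __getitem__(self, idx):
        return take_slice(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = 1
            for a in axes:
                n *= self.shape[a]
        return tsum(self, axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes if axes else None)

    @property
    def T(self):
        return transpose(self, None)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ----------------------------------------------------------------------
# broadcasting helpers
# ----------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = tsum(g, axis=0)
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# ----------------------------------------------------------------------
# arithmetic primitives
# ----------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data + b.data

    def vjp(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return Tensor(out_data, (a, b), vjp)


def neg(a: Tensor) -> Tensor:
    a = astensor(a)
    return Tensor(-a.data, (a,), lambda g: (mul_const(g, -1.0),))


def mul_const(a: Tensor, c: float) -> Tensor:
    a = astensor(a)
    return Tensor(a.data * c, (a,), lambda g: (mul_const(g, c),))


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data * b.data

    def vjp(g):
        return _unbroadcast(mul(g, b), a.shape), _unbroadcast(mul(g, a), b.shape)

    return Tensor(out_data, (a, b), vjp)


def power(a: Tensor, k: float) -> Tensor:
    """Elementwise ``a ** k`` for a constant exponent."""
    a = astensor(a)
    out_data = a.data**k

    def vjp(g):
        return (mul(g, mul_const(power(a, k - 1.0), k)),)

    return Tensor(out_data, (a,), vjp)


def exp(a: Tensor) -> Tensor:
    a = astensor(a)
    out = Tensor(np.exp(a.data), (a,), None)
    out.vjp = lambda g: (mul(g, out),)
    return out


def log(a: Tensor) -> Tensor:
    a = astensor(a)
    return Tensor(np.log(a.data), (a,), lambda g: (mul(g, power(a, -1.0)),))


def sqrt(a: Tensor) -> Tensor:
    return power(a, 0.5)


def tabs(a: Tensor) -> Tensor:
    a = astensor(a)
    sign = np.sign(a.data)
    return Tensor(np.abs(a.data), (a,), lambda g: (mul(g, Tensor(sign)),))


def relu(a: Tensor) -> Tensor:
    a = astensor(a)
    mask = (a.data > 0).astype(np.float64)
    return Tensor(a.data * mask, (a,), lambda g: (mul(g, Tensor(mask)),))


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise maximum; on ties the gradient flows to the first input."""
    a, b = astensor(a), astensor(b)
    mask_a = (a.data >= b.data).astype(np.float64)
    mask_b = 1.0 - mask_a
    out_data = np.maximum(a.data, b.data)

    def vjp(g):
        return (
            _unbroadcast(mul(g, Tensor(mask_a)), a.shape),
            _unbroadcast(mul(g, Tensor(mask_b)), b.shape),
        )

    return Tensor(out_data, (a, b), vjp)


def sigmoid(a: Tensor) -> Tensor:
    a = astensor(a)
    return power(add(Tensor(1.0), exp(neg(a))), -1.0)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D matrix product."""
    a, b = astensor(a), astensor(b)
    out_data = a.data @ b.data

    def vjp(g):
        return matmul(g, transpose(b, None)), matmul(transpose(a, None), g)

    return Tensor(out_data, (a, b), vjp)


# ----------------------------------------------------------------------
# reductions and shape ops
# ----------------------------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = astensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            gg = reshape(g, (1,) * a.ndim)
        elif not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            shp = list(a.shape)
            for ax in axes:
                shp[ax % a.ndim] = 1
            gg = reshape(g, tuple(shp))
        else:
            gg = g
        return (broadcast_to(gg, a.shape),)

    return Tensor(out_data, (a,), vjp)


def tmax(a: Tensor, axis: int) -> Tensor:
    """Max along a single axis; gradient routed to the argmax (first on ties)."""
    a = astensor(a)
    idx = np.argmax(a.data, axis=axis)
    onehot = np.zeros(a.shape, dtype=np.float64)
    np.put_along_axis(onehot, np.expand_dims(idx, axis), 1.0, axis=axis)
    out_data = np.max(a.data, axis=axis)

    def vjp(g):
        gg = reshape(g, tuple(np.expand_dims(out_data, axis).shape))
        return (mul(broadcast_to(gg, a.shape), Tensor(onehot)),)

    return Tensor(out_data, (a,), vjp)


def reshape(a: Tensor, shape: tuple) -> Tensor:
    a = astensor(a)
    old_shape = a.shape
    return Tensor(
        a.data.reshape(shape), (a,), lambda g: (reshape(g, old_shape),)
    )


def transpose(a: Tensor, axes=None) -> Tensor:
    a = astensor(a)
    if axes is None:
        axes = tuple(range(a.ndim))[::-1]
    inv = tuple(np.argsort(axes))
    return Tensor(
        np.transpose(a.data, axes), (a,), lambda g: (transpose(g, inv),)
    )


def flip(a: Tensor, axis) -> Tensor:
    a = astensor(a)
    return Tensor(np.flip(a.data, axis=axis), (a,), lambda g: (flip(g, axis),))


def broadcast_to(a: Tensor, shape: tuple) -> Tensor:
    a = astensor(a)
    orig = a.shape
    return Tensor(
        np.broadcast_to(a.data, shape), (a,), lambda g: (_unbroadcast(g, orig),)
    )


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        grads = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(int(lo), int(hi))
            grads.append(take_slice(g, tuple(idx)))
        return tuple(grads)

    return Tensor(out_data, tuple(tensors), vjp)


def pad_constant(a: Tensor, pad_width) -> Tensor:
    a = astensor(a)
    out_data = np.pad(a.data, pad_width)
    idx = tuple(
        slice(lo, lo + n) for (lo, _hi), n in zip(pad_width, a.shape)
    )
    return Tensor(out_data, (a,), lambda g: (take_slice(g, idx),))


def take_slice(a: Tensor, idx) -> Tensor:
    """Basic (slice/int) indexing; VJP scatters into a zero array."""
    a = astensor(a)
    out_data = a.data[idx]
    shape = a.shape

    def vjp(g):
        return (put_slice(g, idx, shape),)

    return Tensor(out_data, (a,), vjp)


def put_slice(g: Tensor, idx, shape: tuple) -> Tensor:
    """Embed ``g`` into zeros of ``shape`` at ``idx`` (adjoint of take_slice)."""
    g = astensor(g)
    out_data = np.zeros(shape, dtype=np.float64)
    np.add.at(out_data, idx, g.data)
    return Tensor(out_data, (g,), lambda gg: (take_slice(gg, idx),))


def gather(a: Tensor, flat_idx: np.ndarray) -> Tensor:
    """``a.ravel()[flat_idx]`` for a constant integer index array."""
    a = astensor(a)
    out_data = a.data.reshape(-1)[flat_idx]
    size, shape = a.size, a.shape

    def vjp(g):
        return (reshape(scatter_add(g, flat_idx, size), shape),)

    return Tensor(out_data, (a,), vjp)


def scatter_add(g: Tensor, flat_idx: np.ndarray, size: int) -> Tensor:
    g = astensor(g)
    out_data = np.zeros(size, dtype=np.float64)
    np.add.at(out_data, flat_idx.reshape(-1), g.data.reshape(-1))
    idx_shape = flat_idx.shape

    def vjp(gg):
        return (reshape(gather(gg, flat_idx.reshape(-1)), g.shape),)

    return Tensor(out_data, (g,), vjp)


# ----------------------------------------------------------------------
# convolution
# ----------------------------------------------------------------------

def _corr2d(x: np.ndarray, w: np.ndarray, padding: int) -> np.ndarray:
    """Stride-1 cross-correlation, NCHW input, OIHW kernel."""
    n, c, h, wd = x.shape
    o, ci, kh, kw = w.shape
    assert c == ci, "channel mismatch"
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    oh, ow = windows.shape[2], windows.shape[3]
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw)
    out = cols @ w.reshape(o, c * kh * kw).T
    return out.reshape(n, oh, ow, o).transpose(0, 3, 1, 2)


def conv2d(x: Tensor, w: Tensor, padding: int = 0) -> Tensor:
    """Stride-1 2-D cross-correlation of NCHW ``x`` with OIHW kernel ``w``.

    The VJPs are themselves convolutions, so second derivatives (needed
    for gradient penalties) are supported.
    """
    x, w = astensor(x), astensor(w)
    out_data = _corr2d(x.data, w.data, padding)
    kh = w.shape[2]

    def vjp(g):
        w_flip = transpose(flip(flip(w, 2), 3), (1, 0, 2, 3))
        gx = conv2d(g, w_flip, padding=kh - 1 - padding)
        xt = transpose(x, (1, 0, 2, 3))
        gt = transpose(g, (1, 0, 2, 3))
        gw = transpose(conv2d(xt, gt, padding=padding), (1, 0, 2, 3))
        return gx, gw

    return Tensor(out_data, (x, w), vjp)


# ----------------------------------------------------------------------
# backward pass
# ----------------------------------------------------------------------

def grad(output: Tensor, inputs: Sequence[Tensor]) -> list[Tensor]:
    """Gradients of a scalar ``output`` with respect to ``inputs``.

    The returned gradients are graph nodes; calling :func:`grad` on a
    scalar function of them yields second derivatives.
    """
    if output.size != 1:
        raise ValueError("grad expects a scalar output")
    inputs = list(inputs)

    # topological order over the subgraph that requires grad
    topo: list[Tensor] = []
    visited: set[int] = set()
    stack = [(output, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in visited or not node.requires_grad:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if p.requires_grad and id(p) not in visited:
                stack.append((p, False))

    grads: dict[int, Tensor] = {
        id(output): Tensor(np.ones(output.shape, dtype=np.float64))
    }
    for node in reversed(topo):
        g = grads.get(id(node))
        if g is None or node.vjp is None:
            continue
        parent_grads = node.vjp(g)
        for p, pg in zip(node.parents, parent_grads):
            if pg is None or not p.requires_grad:
                continue
            if id(p) in grads:
                grads[id(p)] = add(grads[id(p)], pg)
            else:
                grads[id(p)] = pg

    out = []
    for t in inputs:
        g = grads.get(id(t))
        if g is None:
            g = Tensor(np.zeros(t.shape, dtype=np.float64))
        out.append(g)
    return out
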