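"""A compact reverse-mode automatic-differentiation engine on numpy arrays.

This is the numerical substrate for the package's trainable components (the
synthesis GAN, the teacher/student regressors and the transformer
aggregator): a :class:`Tensor` wraps an ``ndarray`` and records the operation
graph, ``backward()`` accumulates gradients by reverse topological traversal.
Only the operations those models need are provided - elementwise arithmetic
with broadcasting, matmul (batched), reductions, shape ops, N-dimensional
convolution, adaptive average pooling, and the usual nonlinearities.
Everything runs in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv_nd", "adaptive_avg_pool"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # --- graph plumbing ----------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        self.grad = g if self.grad is None else self.grad + g

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # --- arithmetic --------------------------------------------------------
    def __add__(self, other):
        a, b = self, self._lift(other)

        def back(g):
            a._accum(_unbroadcast(g, a.shape))
            b._accum(_unbroadcast(g, b.shape))

        return self._make(a.data + b.data, (a, b), back)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return self._make(-a.data, (a,), lambda g: a._accum(-g))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, self._lift(other)

        def back(g):
            a._accum(_unbroadcast(g * b.data, a.shape))
            b._accum(_unbroadcast(g * a.data, b.shape))

        return self._make(a.data * b.data, (a, b), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, self._lift(other)

        def back(g):
            a._accum(_unbroadcast(g / b.data, a.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return self._make(a.data / b.data, (a, b), back)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, k: float):
        a = self
        return self._make(a.data ** k, (a,),
                          lambda g: a._accum(g * k * a.data ** (k - 1)))

    def __matmul__(self, other):
        a, b = self, self._lift(other)

        def back(g):
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            a._accum(_unbroadcast(ga, a.shape))
            b._accum(_unbroadcast(gb, b.shape))

        return self._make(np.matmul(a.data, b.data), (a, b), back)

    # --- elementwise nonlinearities ----------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return self._make(out_data, (a,), lambda g: a._accum(g * out_data))

    def log(self):
        a = self
        return self._make(np.log(a.data), (a,), lambda g: a._accum(g / a.data))

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)
        return self._make(out_data, (a,), lambda g: a._accum(g * (1 - out_data ** 2)))

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))
        return self._make(out_data, (a,), lambda g: a._accum(g * out_data * (1 - out_data)))

    def relu(self):
        a = self
        mask = a.data > 0
        return self._make(a.data * mask, (a,), lambda g: a._accum(g * mask))

    def leaky_relu(self, slope: float = 0.2):
        a = self
        f = np.where(a.data > 0, 1.0, slope)
        return self._make(a.data * f, (a,), lambda g: a._accum(g * f))

    def abs(self):
        a = self
        s = np.sign(a.data)
        return self._make(np.abs(a.data), (a,), lambda g: a._accum(g * s))

    def sqrt(self):
        return self ** 0.5

    # --- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def back(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
            else:
                ge = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(ge, a.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), back)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[i] for i in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # --- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return self._make(a.data.reshape(shape), (a,),
                          lambda g: a._accum(g.reshape(a.shape)))

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return self._make(a.data.transpose(axes), (a,),
                          lambda g: a._accum(g.transpose(inv)))

    def swapaxes(self, ax1: int, ax2: int):
        a = self
        return self._make(np.swapaxes(a.data, ax1, ax2), (a,),
                          lambda g: a._accum(np.swapaxes(g, ax1, ax2)))

    def __getitem__(self, key):
        a = self

        def back(g):
            gx = np.zeros(a.shape)
            np.add.at(gx, key, g)
            a._accum(gx)

        return self._make(a.data[key], (a,), back)

    @staticmethod
    def concatenate(tensors, axis: int = 0):
        tensors = [Tensor._lift(t) for t in tensors]
        sizes = [t.shape[axis] for t in tensors]
        offs = np.cumsum([0] + sizes)

        def back(g):
            for t, lo, hi in zip(tensors, offs[:-1], offs[1:]):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

        data = np.concatenate([t.data for t in tensors], axis=axis)
        out = Tensor(data)
        out.requires_grad = any(t.requires_grad for t in tensors)
        if out.requires_grad:
            out._parents = tuple(tensors)
            out._backward = back
        return out

    # --- composite helpers ---------------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self - self.data.max(axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = -1):
        shifted = self - self.data.max(axis=axis, keepdims=True)
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def _offset_slices(k: tuple[int, ...], stride: tuple[int, ...],
                   out_sp: tuple[int, ...]):
    """For each kernel offset, the strided slice of the padded input that
    aligns with the full output grid."""
    for off in np.ndindex(*k):
        yield off, tuple(slice(d, d + s * o, s) for d, s, o in zip(off, stride, out_sp))


def conv_nd(x: Tensor, w: Tensor, b: Tensor | None = None,
            stride: int | tuple[int, ...] = 1, padding: int | tuple[int, ...] = 0) -> Tensor:
    """N-dimensional convolution (cross-correlation), channels-first layout.

    ``x``: (N, Cin, *spatial), ``w``: (Cout, Cin, *kernel), optional bias
    (Cout,).  Strides/paddings may be scalars or per-axis tuples.  Forward
    and both gradients are computed as one matmul per kernel offset over
    strided views, so memory stays at the size of the activations.
    """
    nd = x.ndim - 2
    stride = (stride,) * nd if np.isscalar(stride) else tuple(stride)
    padding = (padding,) * nd if np.isscalar(padding) else tuple(padding)
    k = w.shape[2:]
    c_out, c_in = w.shape[:2]
    n = x.shape[0]

    pad_width = ((0, 0), (0, 0)) + tuple((p, p) for p in padding)
    xp = np.pad(x.data, pad_width) if any(padding) else x.data
    out_sp = tuple((i + 2 * p - kk) // s + 1
                   for i, p, kk, s in zip(x.shape[2:], padding, k, stride))
    npos = int(np.prod(out_sp))

    y2 = np.zeros((n, c_out, npos))
    for off, sl in _offset_slices(k, stride, out_sp):
        xs = xp[(slice(None), slice(None)) + sl].reshape(n, c_in, npos)
        y2 += np.swapaxes(np.tensordot(w.data[(...,) + off], xs, axes=(1, 1)), 0, 1)
    y = y2.reshape((n, c_out) + out_sp)

    def back(g):
        g2 = g.reshape(n, c_out, npos)
        if w.requires_grad:
            gw = np.zeros(w.shape)
            for off, sl in _offset_slices(k, stride, out_sp):
                xs = xp[(slice(None), slice(None)) + sl].reshape(n, c_in, npos)
                gw[(...,) + off] = np.tensordot(g2, xs, axes=([0, 2], [0, 2]))
            w._accum(gw)
        if x.requires_grad:
            gxp = np.zeros(xp.shape)
            for off, sl in _offset_slices(k, stride, out_sp):
                contrib = np.tensordot(w.data[(...,) + off], g2, axes=(0, 1))  # (cin,n,npos)
                gxp[(slice(None), slice(None)) + sl] += np.swapaxes(
                    contrib, 0, 1).reshape((n, c_in) + out_sp)
            crop = tuple(slice(p, p + i) for p, i in zip(padding, x.shape[2:]))
            x._accum(gxp[(slice(None), slice(None)) + crop])

    out = x._make(y, (x, w), back)
    if b is not None:
        out = out + b.reshape((1, -1) + (1,) * nd)
    return out


def adaptive_avg_pool(x: Tensor, out_size: tuple[int, ...]) -> Tensor:
    """Average-pool the spatial axes of (N, C, *spatial) onto ``out_size``
    using contiguous integer bins (the standard adaptive scheme)."""
    sp = x.shape[2:]
    nd = len(sp)
    if len(out_size) != nd:
        raise ValueError("out_size rank must match the spatial rank")
    # torch-style bins: start = floor(i n / o), end = ceil((i+1) n / o) -- never empty
    bounds = [(np.floor(np.arange(o) * n / o).astype(int),
               np.ceil((np.arange(o) + 1) * n / o).astype(int)) for n, o in zip(sp, out_size)]
    y = np.zeros(x.shape[:2] + tuple(out_size))
    cells = list(np.ndindex(*out_size))
    slices = []
    for cell in cells:
        sl = tuple(slice(lo[i], hi[i]) for (lo, hi), i in zip(bounds, cell))
        slices.append(sl)
        y[(slice(None), slice(None)) + cell] = x.data[(slice(None), slice(None)) + sl].mean(
            axis=tuple(range(2, 2 + nd)))

    def back(g):
        gx = np.zeros(x.shape)
        for cell, sl in zip(cells, slices):
            n = np.prod([s.stop - s.start for s in sl])
            gx[(slice(None), slice(None)) + sl] += (
                g[(slice(None), slice(None)) + cell][(Ellipsis,) + (None,) * nd] / n)
        x._accum(gx)

    return x._make(y, (x,), back)
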