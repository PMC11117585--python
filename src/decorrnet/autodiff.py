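"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical core the network layers and training objectives are
built on.  It implements exactly the operations the architectures in
:mod:`decorrnet.models` and the penalties in :mod:`decorrnet.dcor` need:
elementwise arithmetic with broadcasting, matrix products, reductions,
reshapes/concatenation, 2-D convolution (im2col), max-pooling, and the
activations used by convolutional GRU gates.

Gradients are accumulated by a topological-order sweep over the recorded
graph.  All computation is float64 numpy, so runs are bitwise deterministic
for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows", "conv2d", "maxpool2d",
           "log_softmax", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(),
                 backward=None, name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    # -- graph mechanics ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep (ConvGRU over T frames)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in node._backward(g):
                if parent._backward is None and not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- construction helpers ---------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- elementwise arithmetic -------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data
        def bw(g):
            return ((self, _unbroadcast(g, self.shape)),
                    (other, _unbroadcast(g, other.shape)))
        return Tensor(out_data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward=lambda g: ((self, -g),))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data
        def bw(g):
            return ((self, _unbroadcast(g * other.data, self.shape)),
                    (other, _unbroadcast(g * self.data, other.shape)))
        return Tensor(out_data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out_data = self.data / other.data
        def bw(g):
            return ((self, _unbroadcast(g / other.data, self.shape)),
                    (other, _unbroadcast(-g * self.data / other.data ** 2,
                                         other.shape)))
        return Tensor(out_data, parents=(self, other), backward=bw)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p
        def bw(g):
            return ((self, g * p * self.data ** (p - 1)),)
        return Tensor(out_data, parents=(self,), backward=bw)

    def square(self):
        def bw(g):
            return ((self, g * 2.0 * self.data),)
        return Tensor(self.data ** 2, parents=(self,), backward=bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)
        def bw(g):
            return ((self, g * 0.5 / np.maximum(out_data, 1e-300)),)
        return Tensor(out_data, parents=(self,), backward=bw)

    def exp(self):
        out_data = np.exp(self.data)
        def bw(g):
            return ((self, g * out_data),)
        return Tensor(out_data, parents=(self,), backward=bw)

    def log(self):
        def bw(g):
            return ((self, g / self.data),)
        return Tensor(np.log(self.data), parents=(self,), backward=bw)

    def relu(self):
        mask = self.data > 0
        def bw(g):
            return ((self, g * mask),)
        return Tensor(self.data * mask, parents=(self,), backward=bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        def bw(g):
            return ((self, g * out_data * (1.0 - out_data)),)
        return Tensor(out_data, parents=(self,), backward=bw)

    def tanh(self):
        out_data = np.tanh(self.data)
        def bw(g):
            return ((self, g * (1.0 - out_data ** 2)),)
        return Tensor(out_data, parents=(self,), backward=bw)

    # -- linear algebra ----------------------------------------------------

    def matmul(self, other: "Tensor"):
        other = Tensor._lift(other)
        out_data = self.data @ other.data
        def bw(g):
            return ((self, g @ other.data.T), (other, self.data.T @ g))
        return Tensor(out_data, parents=(self, other), backward=bw)

    __matmul__ = matmul

    @property
    def T(self):
        def bw(g):
            return ((self, g.T),)
        return Tensor(self.data.T, parents=(self,), backward=bw)

    # -- reductions / shaping ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def bw(g):
            g = np.asarray(g)
            if axis is None:
                return ((self, np.broadcast_to(g, shape).copy()),)
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                for ax in sorted(a % len(shape) for a in axes):
                    g = np.expand_dims(g, ax)
            return ((self, np.broadcast_to(g, shape).copy()),)
        return Tensor(out_data, parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        def bw(g):
            return ((self, g.reshape(old)),)
        return Tensor(self.data.reshape(shape), parents=(self,), backward=bw)

    def transpose(self, axes):
        inv = np.argsort(axes)
        def bw(g):
            return ((self, g.transpose(inv)),)
        return Tensor(self.data.transpose(axes), parents=(self,), backward=bw)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        out = []
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, b)
            out.append((t, g[tuple(idx)]))
        return tuple(out)
    return Tensor(out_data, parents=tuple(tensors), backward=bw)


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """Select rows (axis 0) of ``x``; backward scatter-adds into place."""
    index = np.asarray(index, dtype=np.intp)

    def bw(g):
        full = np.zeros_like(x.data)
        np.add.at(full, index, g)
        return ((x, full),)
    return Tensor(x.data[index], parents=(x,), backward=bw)


# -- spatial ops -----------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N*H*W, C*kh*kw) patch matrix, stride 1, zero padding."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # win: (N, C, H, W, kh, kw) -> (N, H, W, C, kh, kw)
    n, c, h, w = x.shape[0], x.shape[1], win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * kh * kw)
    return np.ascontiguousarray(cols)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """'Same' 2-D convolution, stride 1.

    ``x``: (N, C, H, W); ``weight``: (F, C, kh, kw); ``bias``: (F,).
    """
    n, c, h, w = x.shape
    f, cw, kh, kw = weight.shape
    if cw != c:
        raise ValueError(f"channel mismatch: input {c}, weight {cw}")
    pad = (kh - 1) // 2
    cols = _im2col(x.data, kh, kw, pad)                    # (NHW, Ckk)
    wmat = weight.data.reshape(f, c * kh * kw)             # (F, Ckk)
    out = cols @ wmat.T + bias.data                        # (NHW, F)
    out = out.reshape(n, h, w, f).transpose(0, 3, 1, 2)

    def bw(g):
        gm = g.transpose(0, 2, 3, 1).reshape(n * h * w, f)   # (NHW, F)
        gw = (gm.T @ cols).reshape(weight.shape)
        gb = gm.sum(axis=0)
        gcols = gm @ wmat                                    # (NHW, Ckk)
        gcols = gcols.reshape(n, h, w, c, kh, kw)
        gx = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
        for i in range(kh):                                  # scatter-add col2im
            for j in range(kw):
                gx[:, :, i:i + h, j:j + w] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        gx = gx[:, :, pad:pad + h, pad:pad + w]
        return ((x, gx), (weight, gw), (bias, gb))
    return Tensor(out, parents=(x, weight, bias), backward=bw)


def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    """Max-pooling with window = stride = ``k``; trailing rows/cols dropped."""
    n, c, h, w = x.shape
    ho, wo = h // k, w // k
    xc = x.data[:, :, :ho * k, :wo * k]
    blocks = xc.reshape(n, c, ho, k, wo, k).transpose(0, 1, 2, 4, 3, 5)
    blocks = blocks.reshape(n, c, ho, wo, k * k)
    arg = blocks.argmax(axis=-1)
    out = np.take_along_axis(blocks, arg[..., None], axis=-1)[..., 0]

    def bw(g):
        gb = np.zeros((n, c, ho, wo, k * k))
        np.put_along_axis(gb, arg[..., None], g[..., None], axis=-1)
        gb = gb.reshape(n, c, ho, wo, k, k).transpose(0, 1, 2, 4, 3, 5)
        gx = np.zeros_like(x.data)
        gx[:, :, :ho * k, :wo * k] = gb.reshape(n, c, ho * k, wo * k)
        return ((x, gx),)
    return Tensor(out, parents=(x,), backward=bw)


def log_softmax(logits: Tensor) -> Tensor:
    """Row-wise log-softmax with the max-shift trick (fused, stable)."""
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    sez = ez.sum(axis=1, keepdims=True)
    out = (z - zmax) - np.log(sez)
    p = ez / sez

    def bw(g):
        return ((logits, g - p * g.sum(axis=1, keepdims=True)),)
    return Tensor(out, parents=(logits,), backward=bw)


def softmax(logits: Tensor) -> Tensor:
    return log_softmax(logits).exp()
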