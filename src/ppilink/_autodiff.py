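"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the model needs: broadcast arithmetic,
(batched) matrix products, reductions, elementwise nonlinearities, softmax,
concatenation/reshaping/gathering, same-padded 1-D convolution and 1-D max
pooling. Everything is float64 so that analytic gradients can be validated
against central finite differences at tight tolerances.

A ``Tensor`` wraps an ndarray and records the closure needed to push its
output gradient back to its parents; ``Tensor.backward()`` runs a topological
sweep. Gradient recording can be suspended with ``no_grad()`` for inference.
"""

from __future__ import annotations

import numpy as np

_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables gradient-tape construction."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast from ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    for _ in range(extra):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g) -> None:
        g = np.asarray(g, dtype=np.float64)
        self.grad = g if self.grad is None else self.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        )
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        a, b = self, Tensor._lift(other)

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            a._accum(-g)

        return Tensor._make(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other)

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor._make(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        a = self

        def bwd(g):
            a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(a.data**p, (a,), bwd)

    def __matmul__(self, other):
        a, b = self, Tensor._lift(other)
        # both operands must be at least 2-D; batching via broadcasting is fine
        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g @ b.data.swapaxes(-1, -2), a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(a.data.swapaxes(-1, -2) @ g, b.shape))

        return Tensor._make(a.data @ b.data, (a, b), bwd)

    # -- reductions / shaping ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).astype(np.float64, copy=False))

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bwd(g):
            a._accum(g.reshape(a.shape))

        return Tensor._make(a.data.reshape(shape), (a,), bwd)

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g):
            a._accum(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), bwd)

    def __getitem__(self, idx):
        a = self

        def bwd(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return Tensor._make(a.data[idx], (a,), bwd)

    # -- elementwise nonlinearities -------------------------------------------

    def relu(self):
        a = self
        mask = a.data > 0

        def bwd(g):
            a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), bwd)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bwd(g):
            a._accum(g * (1.0 - out_data * out_data))

        return Tensor._make(out_data, (a,), bwd)

    def sigmoid(self):
        a = self
        x = a.data
        out_data = np.empty_like(x)
        pos = x >= 0
        out_data[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out_data[~pos] = ex / (1.0 + ex)

        def bwd(g):
            a._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), bwd)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            a._accum(g * out_data)

        return Tensor._make(out_data, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bwd)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bwd(g):
            a._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (a,), bwd)

    def clip(self, lo: float, hi: float):
        a = self
        mask = (a.data > lo) & (a.data < hi)

        def bwd(g):
            a._accum(g * mask)

        return Tensor._make(np.clip(a.data, lo, hi), (a,), bwd)

    def softmax(self, axis: int = -1):
        a = self
        shifted = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        p = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            a._accum(p * (g - (g * p).sum(axis=axis, keepdims=True)))

        return Tensor._make(p, (a,), bwd)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            if t.requires_grad:
                t._accum(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, bwd
    )


def conv1d_same(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 1-D convolution.

    x: (B, C_in, L), w: (C_out, C_in, k), b: (C_out,) or None -> (B, C_out, L).
    Padding is with zeros on both sides (k odd).
    """
    x, w = Tensor._lift(x), Tensor._lift(w)
    B, C_in, L = x.shape
    C_out, C_in_w, k = w.shape
    if C_in != C_in_w:
        raise ValueError(f"conv1d_same: input has {C_in} channels, kernel expects {C_in_w}")
    if L < 1:
        raise ValueError("conv1d_same: sequence length must be >= 1")
    pad = k // 2
    xp = np.zeros((B, C_in, L + 2 * pad))
    xp[:, :, pad : pad + L] = x.data
    # direct form: sum of k kernel-slice matmuls on shifted views (no im2col
    # copy — faster than im2col at small channel counts)
    wd = w.data
    out_data = np.matmul(wd[:, :, 0], xp[:, :, 0:L])
    for t in range(1, k):
        out_data += np.matmul(wd[:, :, t], xp[:, :, t : t + L])

    parents = [x, w]
    if b is not None:
        b = Tensor._lift(b)
        out_data = out_data + b.data[None, :, None]
        parents.append(b)

    def bwd(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if w.requires_grad:
            gT = g.swapaxes(1, 2)  # (B, L, C_out)
            dw = np.empty((C_out, C_in, k))
            for t in range(k):
                dw[:, :, t] = np.matmul(xp[:, :, t : t + L], gT).sum(axis=0).T
            w._accum(dw)
        if x.requires_grad:
            dxp = np.zeros((B, C_in, L + 2 * pad))
            for t in range(k):
                dxp[:, :, t : t + L] += np.matmul(wd[:, :, t].T, g)
            x._accum(dxp[:, :, pad : pad + L])

    return Tensor._make(out_data, parents, bwd)


def maxpool1d_same(x: Tensor, k: int = 3) -> Tensor:
    """Same-padded stride-1 1-D max pooling over the temporal axis.

    Padding is with zeros (documented convention: boundary windows may take
    the pad value 0 when all in-window activations are negative; no gradient
    flows to pad positions).
    """
    x = Tensor._lift(x)
    B, C, L = x.shape
    pad = k // 2
    xp = np.zeros((B, C, L + 2 * pad))
    xp[:, :, pad : pad + L] = x.data
    slices = [xp[:, :, t : t + L] for t in range(k)]
    out_data = slices[0].copy()
    for s in slices[1:]:
        np.maximum(out_data, s, out=out_data)

    def bwd(g):
        if x.requires_grad:
            dxp = np.zeros((B, C, L + 2 * pad))
            taken = np.zeros((B, C, L), dtype=bool)
            for t in range(k):  # first maximal position wins the gradient
                m = (slices[t] == out_data) & ~taken
                dxp[:, :, t : t + L] += g * m
                taken |= m
            x._accum(dxp[:, :, pad : pad + L])

    return Tensor._make(out_data, (x,), bwd)


def glorot(rng, shape) -> Tensor:
    fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def he(rng, shape, fan_in: int) -> Tensor:
    return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape), requires_grad=True)


class Adam:
    """Adam optimizer (Kingma & Ba) over a list of trainable Tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * (g * g)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
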