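"""Minimal reverse-mode automatic differentiation over numpy arrays.

All learnable computation in this package (generator, discriminator, losses)
runs through :class:`Tensor`, a thin float32 ndarray wrapper that records a
tape of operations and back-propagates with hand-written adjoints.  Only the
operations the super-resolution networks actually need are implemented; the
design goal is a small, deterministic, CPU-only engine, not a general
framework.

Conventions
-----------
* feature maps are ``(batch, channel, height, width)`` float32 arrays;
* gradients accumulate into ``Tensor.grad`` (same shape as ``data``);
* broadcasting follows numpy; adjoints un-broadcast by summing.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack_sum"]

_F32 = np.float32


def _as_f32(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype != _F32:
        a = a.astype(_F32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (adjoint of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_f32(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ---------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(_F32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(_as_f32(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate grads/tape as we go
                if node._parents:
                    node.grad = None
        # leaf grads remain

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- conveniences -----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- elementwise arithmetic -------------------------------------------

    def __add__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g, o.data.shape))

        return Tensor._make(self.data + o.data, (self, o), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(-g, o.data.shape))

        return Tensor._make(self.data - o.data, (self, o), bwd)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * o.data, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g * self.data, o.data.shape))

        return Tensor._make(self.data * o.data, (self, o), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / o.data, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(-g * self.data / (o.data * o.data), o.data.shape))

        return Tensor._make(self.data / o.data, (self, o), bwd)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        def bwd(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), bwd)

    # -- nonlinearities -----------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            self._accum(g * (0.5 / np.maximum(out_data, 1e-12)))

        return Tensor._make(out_data, (self,), bwd)

    def abs(self):
        sign = np.sign(self.data)

        def bwd(g):
            self._accum(g * sign)

        return Tensor._make(np.abs(self.data), (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        scale = np.where(mask, _F32(1.0), _F32(slope))

        def bwd(g):
            self._accum(g * scale)

        return Tensor._make(self.data * scale, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        out_data = out_data.astype(_F32)

        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bwd)

    def clip01(self):
        """Clamp to [0,1]; pass-through gradient strictly inside the range."""
        mask = (self.data > 0.0) & (self.data < 1.0)

        def bwd(g):
            self._accum(g * mask)

        return Tensor._make(np.clip(self.data, 0.0, 1.0), (self,), bwd)

    # -- reductions / shape -------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).astype(_F32))

        return Tensor._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = 1
            for a in axes:
                n *= self.data.shape[a]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bwd(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), bwd)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bwd)

    def __getitem__(self, idx):
        def bwd(g):
            gg = np.zeros_like(self.data)
            gg[idx] = g
            self._accum(gg)

        return Tensor._make(self.data[idx], (self,), bwd)

    def pad2d(self, ph: int, pw: int):
        """Zero-pad the last two axes by (ph, pw) on each side."""
        if ph == 0 and pw == 0:
            return self
        pads = [(0, 0)] * (self.data.ndim - 2) + [(ph, ph), (pw, pw)]

        def bwd(g):
            sl = tuple([slice(None)] * (self.data.ndim - 2) + [slice(ph, g.shape[-2] - ph), slice(pw, g.shape[-1] - pw)])
            self._accum(g[sl])

        return Tensor._make(np.pad(self.data, pads), (self,), bwd)

    # -- composites ---------------------------------------------------------

    def prelu(self, alpha: "Tensor"):
        """max(0,x) + alpha*min(0,x); alpha broadcast (per-channel or scalar)."""
        return self.relu() - alpha * (-self).relu()

    def softmax(self, axis: int):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


def concat(tensors, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offs = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), bwd)


def stack_sum(tensors) -> Tensor:
    """Sum of a list of same-shaped tensors (fewer graph nodes than chained +)."""
    def bwd(g):
        for t in tensors:
            if t.requires_grad:
                t._accum(g)

    return Tensor._make(np.sum([t.data for t in tensors], axis=0), tuple(tensors), bwd)
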