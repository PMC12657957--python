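"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine provides exactly the operator set the dwell-time model needs:
broadcasting arithmetic, (batched) matmul, elementwise transcendentals,
reductions, reshaping, fancy indexing (which doubles as embedding lookup
and attention-score gather), and concatenation.  Gradients are accumulated
by a topological walk over the recorded tape.

Float dtype follows the input arrays; the model runs in float32 for speed
and in float64 when gradients are checked against finite differences.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording inside the block (inference / IG baselines)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # the tape is single-use; free intermediates eagerly
                node._backward = None
                node._parents = ()

    def _accum(self, g):
        g = _unbroadcast(g, self.data.shape).astype(self.data.dtype, copy=False)
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic --------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))

        def bwd(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))

        def bwd(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(-g)

        return Tensor._make(self.data - other.data, (self, other), bwd)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / (other.data * other.data))

        return Tensor._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        def bwd(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), bwd)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                while ga.ndim > self.data.ndim:
                    ga = ga.sum(axis=0)
                self._accum(ga)
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                while gb.ndim > other.data.ndim:
                    gb = gb.sum(axis=0)
                other._accum(gb)

        return Tensor._make(np.matmul(self.data, other.data), (self, other), bwd)

    # -- elementwise -------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            self._accum(g * (1.0 - out_data * out_data))

        return Tensor._make(out_data, (self,), bwd)

    def arctan(self):
        def bwd(g):
            self._accum(g / (1.0 + self.data * self.data))

        return Tensor._make(np.arctan(self.data), (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), bwd)

    def abs(self):
        def bwd(g):
            self._accum(g * np.sign(self.data))

        return Tensor._make(np.abs(self.data), (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def gelu(self):
        """Gaussian-error linear unit (tanh form). Smooth, so path-integral
        attributions of the network converge fast in the step count."""
        c = 0.7978845608028654  # sqrt(2/pi)
        x = self.data
        inner = x * x
        inner *= 0.044715 * c * x
        inner += c * x
        th = np.tanh(inner)

        def bwd(g):
            sech2 = 1.0 - th * th
            d_inner = c * (1.0 + 3 * 0.044715 * x * x)
            self._accum(g * (0.5 * (1.0 + th) + 0.5 * x * sech2 * d_inner))

        return Tensor._make(0.5 * x * (1.0 + th), (self,), bwd)

    # -- reductions & shaping ----------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            denom = self.data.size
        else:
            denom = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / denom)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bwd(g):
            self._accum(g.reshape(self.data.shape))

        return Tensor._make(self.data.reshape(shape), (self,), bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bwd)

    def __getitem__(self, key):
        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)

        return Tensor._make(self.data[key], (self,), bwd)


def cat(tensors, axis=0):
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd
    )


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax with a fused closed-form backward."""
    z = t.data - t.data.max(axis=axis, keepdims=True)
    np.exp(z, out=z)
    z /= z.sum(axis=axis, keepdims=True)
    s = z

    def bwd(g):
        gs = g * s
        t._accum(gs - s * gs.sum(axis=axis, keepdims=True))

    return Tensor._make(s, (t,), bwd)


def band_gather(qr: Tensor, n: int) -> Tensor:
    """out[..., i, j] = qr[..., i, i - j + n - 1] for qr with last axis 2n-1.

    Collects the relative-position score band; the index map is injective,
    so the backward pass is a plain fancy assignment.
    """
    ii = np.arange(n)[:, None]
    idx = ii - np.arange(n)[None, :] + n - 1
    key = (Ellipsis, ii, idx)

    def bwd(g):
        full = np.zeros_like(qr.data)
        full[key] = g
        qr._accum(full)

    return Tensor._make(qr.data[key], (qr,), bwd)


class Adam:
    """Adam with optional per-step learning-rate override (for cosine decay)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self, lr=None):
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= (lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(
                p.data.dtype
            )
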