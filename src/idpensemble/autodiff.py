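"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the denoising network needs: broadcasting
arithmetic, two-operand einsum, reductions, shape ops, pointwise
nonlinearities, softmax/layer-norm building blocks, and a piecewise-linear
table lookup with a supplied derivative table (used for the IGSO3 score).

Gradients are accumulated by topological traversal of the recorded graph.
A module-level switch (:func:`no_grad`) disables graph recording entirely,
which is how inference/sampling avoids the bookkeeping cost.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_grad_enabled = True


@contextmanager
def no_grad():
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum grad down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self._backward = None
        self._parents = ()

    # -- construction ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph ----------------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        # grads are never mutated in place, so taking a reference is safe
        if self.grad is None:
            self.grad = g if g.dtype == self.data.dtype else g.astype(self.data.dtype)
        else:
            self.grad = self.grad + g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add,
                       lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda g, a, b: g * b.data, lambda g, a, b: g * a.data)

    __rmul__ = __mul__

    def __sub__(self, other):
        return _binary(self, other, np.subtract,
                       lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __neg__(self):
        return self * (-1.0)

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p
        return _unary(self, out_data, lambda g: g * p * self.data ** (p - 1))

    # -- pointwise ------------------------------------------------------------
    def exp(self):
        out = np.exp(self.data)
        return _unary(self, out, lambda g: g * out)

    def log(self):
        return _unary(self, np.log(self.data), lambda g: g / self.data)

    def sqrt(self):
        out = np.sqrt(self.data)
        return _unary(self, out, lambda g: g * 0.5 / np.maximum(out, 1e-30))

    def sin(self):
        return _unary(self, np.sin(self.data), lambda g: g * np.cos(self.data))

    def cos(self):
        return _unary(self, np.cos(self.data), lambda g: -g * np.sin(self.data))

    def tanh(self):
        out = np.tanh(self.data)
        return _unary(self, out, lambda g: g * (1 - out * out))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))
        return _unary(self, out, lambda g: g * out * (1 - out))

    def relu(self):
        mask = self.data > 0
        return _unary(self, self.data * mask, lambda g: g * mask)

    def gelu(self):
        # tanh approximation
        x = self.data
        c = np.sqrt(2.0 / np.pi)
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out = 0.5 * x * (1 + t)

        def back(g):
            dinner = c * (1 + 3 * 0.044715 * x**2)
            return g * (0.5 * (1 + t) + 0.5 * x * (1 - t * t) * dinner)

        return _unary(self, out, back)

    def softplus(self):
        out = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-self.data))
        return _unary(self, out, lambda g: g * sig)

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        return _unary(self, np.clip(self.data, lo, hi), lambda g: g * mask)

    def arccos(self):
        x = np.clip(self.data, -1.0 + 1e-7, 1.0 - 1e-7)
        return _unary(self, np.arccos(x), lambda g: -g / np.sqrt(1.0 - x * x))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, self.data.shape)

        return _unary(self, out, back)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ----------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return _unary(self, self.data.reshape(shape),
                      lambda g: g.reshape(self.data.shape))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return _unary(self, self.data.transpose(axes),
                      lambda g: g.transpose(inv))

    def __getitem__(self, idx):
        out = self.data[idx]

        def back(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return full

        return _unary(self, out, back)

    # -- linear algebra ---------------------------------------------------------
    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def back_a(g, a, b):
            return _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape)

        def back_b(g, a, b):
            return _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape)

        return _binary(self, other, None, back_a, back_b, out_data=out_data)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unary(a: Tensor, out_data: np.ndarray, back) -> Tensor:
    out = Tensor(out_data)
    if _grad_enabled and a.requires_grad:
        out.requires_grad = True
        out._parents = (a,)
        out._backward = lambda g: a._accumulate(_unbroadcast(back(g), a.data.shape))
    return out


def _binary(a, b, fwd, back_a, back_b, out_data=None) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if out_data is None:
        out_data = fwd(a.data, b.data)
    out = Tensor(out_data)
    if _grad_enabled and (a.requires_grad or b.requires_grad):
        out.requires_grad = True
        out._parents = tuple(t for t in (a, b) if t.requires_grad)

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(back_a(g, a, b), a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(back_b(g, a, b), b.data.shape))

        out._backward = backward
    return out


def einsum(eq: str, a, b) -> Tensor:
    """Two-operand einsum with autodiff.

    Every index of each operand must appear in the output or in the other
    operand (no internal traces), which holds for all uses in this package.
    """
    a, b = as_tensor(a), as_tensor(b)
    lhs, out_spec = eq.split("->")
    spec_a, spec_b = lhs.split(",")
    out_data = np.einsum(eq, a.data, b.data, optimize=True)
    out = Tensor(out_data)
    if _grad_enabled and (a.requires_grad or b.requires_grad):
        out.requires_grad = True
        out._parents = tuple(t for t in (a, b) if t.requires_grad)

        def backward(g):
            if a.requires_grad:
                ga = np.einsum(f"{out_spec},{spec_b}->{spec_a}", g, b.data, optimize=True)
                a._accumulate(ga)
            if b.requires_grad:
                gb = np.einsum(f"{out_spec},{spec_a}->{spec_b}", g, a.data, optimize=True)
                b._accumulate(gb)

        out._backward = backward
    return out


def concatenate(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if _grad_enabled and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(t for t in tensors if t.requires_grad)
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accumulate(g[tuple(sl)])

        out._backward = backward
    return out


def stack(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis))
    if _grad_enabled and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(t for t in tensors if t.requires_grad)

        def backward(g):
            parts = np.split(g, len(tensors), axis=axis)
            for t, part in zip(tensors, parts):
                if t.requires_grad:
                    t._accumulate(np.squeeze(part, axis=axis))

        out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Fused softmax with the analytic Jacobian-vector backward."""
    e = np.exp(x.data - x.data.max(axis=axis, keepdims=True))
    y = e / e.sum(axis=axis, keepdims=True)

    def back(g):
        return y * (g - (g * y).sum(axis=axis, keepdims=True))

    return _unary(x, y, back)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Fused layer normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(gamma.data * xhat + beta.data)
    needs = _grad_enabled and (x.requires_grad or gamma.requires_grad or beta.requires_grad)
    if needs:
        out.requires_grad = True
        out._parents = tuple(t for t in (x, gamma, beta) if t.requires_grad)

        def backward(g):
            lead = tuple(range(g.ndim - 1))
            if gamma.requires_grad:
                gamma._accumulate(_unbroadcast((g * xhat).sum(axis=lead), gamma.data.shape))
            if beta.requires_grad:
                beta._accumulate(_unbroadcast(g.sum(axis=lead), beta.data.shape))
            if x.requires_grad:
                dxhat = g * gamma.data
                dx = inv * (
                    dxhat
                    - dxhat.mean(axis=-1, keepdims=True)
                    - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
                )
                x._accumulate(dx)

        out._backward = backward
    return out


def table_lookup(x: Tensor, grid: np.ndarray, values: np.ndarray,
                 slopes: np.ndarray) -> Tensor:
    """Piecewise-linear interpolation values(x) with d/dx from `slopes`.

    `values`/`slopes` may be 1-D (shared) or have a leading batch axis
    matching x's leading axis (per-sample rows).
    """
    xd = np.clip(x.data, grid[0], grid[-1])
    if values.ndim == 1:
        out_data = np.interp(xd, grid, values)
        deriv = np.interp(xd, grid, slopes)
    else:
        out_data = np.empty_like(xd)
        deriv = np.empty_like(xd)
        for i in range(xd.shape[0]):
            out_data[i] = np.interp(xd[i], grid, values[i])
            deriv[i] = np.interp(xd[i], grid, slopes[i])
    return _unary(x, out_data, lambda g: g * deriv)
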