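"""Reverse-mode automatic differentiation over numpy arrays.

The optical simulator is a chain of linear transforms (FFT convolutions,
chirp-z zooms) and pointwise nonlinearities acting on complex field rasters,
terminated by a real scalar loss.  This module provides the tape-based
reverse-mode engine that backpropagates through that chain, including complex
intermediates via Wirtinger calculus.

Conventions
-----------
* Leaves (optimizable parameters) are real arrays.  Complex values appear only
  as intermediates.
* For a real node ``x`` the accumulated cotangent is ``dL/dx``.
* For a complex node ``z`` the cotangent is ``2 * dL/d(conj z)``; with this
  scaling a holomorphic op ``y = f(z)`` has the familiar rule
  ``g_z = g_y * conj(f'(z))`` and the complex→real boundary is simply
  ``g_real = Re(g_complex)`` (taken automatically when a cotangent reaches a
  real-valued node).

Gradients are verified against central finite differences in the test suite,
which is the contract the optimizer relies on.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "as_tensor", "backward",
    "add", "sub", "mul", "div", "neg", "power",
    "exp", "log", "sqrt", "sin", "cos", "tanh", "sigmoid", "softplus",
    "abs2", "real", "imag", "conj",
    "tsum", "tmean", "tmax", "where", "greater",
    "fft2", "ifft2", "fft", "ifft", "pad2", "crop2", "getitem", "reshape",
    "stack", "logsumexp", "clip_min",
]


def _is_complex(v) -> bool:
    return np.iscomplexobj(v)


class Tensor:
    """A node in the computation graph wrapping a numpy array."""

    __slots__ = ("value", "requires_grad", "parents", "grad", "name")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, value, requires_grad: bool = False, parents=(), name: str = ""):
        v = np.asarray(value)
        if v.dtype.kind in "iub":
            v = v.astype(np.float64)
        self.value = v
        self.requires_grad = requires_grad
        self.parents = parents  # tuple of (Tensor, vjp callable)
        self.grad = None
        self.name = name

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def size(self):
        return self.value.size

    @property
    def dtype(self):
        return self.value.dtype

    def detach(self) -> np.ndarray:
        return self.value

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, dtype={self.value.dtype}, grad={self.requires_grad})"

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _track(*ts) -> bool:
    return any(isinstance(t, Tensor) and (t.requires_grad or t.parents) for t in ts)


def _make(value, parents) -> Tensor:
    parents = tuple((p, f) for p, f in parents
                    if isinstance(p, Tensor) and (p.requires_grad or p.parents))
    return Tensor(value, requires_grad=bool(parents), parents=parents)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum cotangent over axes that were broadcast in the forward op."""
    g = np.asarray(g)
    if g.shape == tuple(shape):
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def backward(root: Tensor, seed=None) -> None:
    """Backpropagate from a (real scalar) root, accumulating ``.grad``."""
    if seed is None:
        seed = np.ones_like(root.value, dtype=np.float64)
    # iterative topological order
    topo, visited, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            topo.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p, _ in node.parents:
            if id(p) not in visited:
                stack.append((p, False))
    cot = {id(root): np.asarray(seed)}
    for node in reversed(topo):
        g = cot.pop(id(node), None)
        if g is None:
            continue
        if node.requires_grad and not node.parents:
            acc = g.real if not _is_complex(node.value) and _is_complex(g) else g
            acc = _unbroadcast(acc, node.value.shape)
            node.grad = acc if node.grad is None else node.grad + acc
        for p, vjp in node.parents:
            pg = vjp(g)
            if pg is None:
                continue
            if not _is_complex(p.value) and _is_complex(pg):
                pg = pg.real  # complex→real boundary: Re(g · conj(J))
            key = id(p)
            cot[key] = cot[key] + pg if key in cot else np.asarray(pg)


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    v = a.value + b.value
    return _make(v, [(a, lambda g: _unbroadcast(g, a.value.shape)),
                     (b, lambda g: _unbroadcast(g, b.value.shape))])


def sub(a, b):
    a, b = as_tensor(a), as_tensor(b)
    v = a.value - b.value
    return _make(v, [(a, lambda g: _unbroadcast(g, a.value.shape)),
                     (b, lambda g: _unbroadcast(-g, b.value.shape))])


def neg(a):
    a = as_tensor(a)
    return _make(-a.value, [(a, lambda g: -g)])


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    v = a.value * b.value
    return _make(v, [(a, lambda g: _unbroadcast(g * np.conj(b.value), a.value.shape)),
                     (b, lambda g: _unbroadcast(g * np.conj(a.value), b.value.shape))])


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    v = a.value / b.value
    def ga(g):
        return _unbroadcast(g * np.conj(1.0 / b.value), a.value.shape)
    def gb(g):
        return _unbroadcast(g * np.conj(-a.value / b.value ** 2), b.value.shape)
    return _make(v, [(a, ga), (b, gb)])


def power(a, p: float):
    a = as_tensor(a)
    v = a.value ** p
    return _make(v, [(a, lambda g: g * np.conj(p * a.value ** (p - 1)))])


# ---------------------------------------------------------------------------
# pointwise nonlinearities (holomorphic rule g * conj(f'))
# ---------------------------------------------------------------------------

def _unary(a, v, dfn):
    a = as_tensor(a)
    return _make(v, [(a, lambda g: g * np.conj(dfn()))])


def exp(a):
    a = as_tensor(a)
    v = np.exp(a.value)
    return _unary(a, v, lambda: v)


def log(a):
    a = as_tensor(a)
    return _unary(a, np.log(a.value), lambda: 1.0 / a.value)


def sqrt(a):
    a = as_tensor(a)
    v = np.sqrt(a.value)
    return _unary(a, v, lambda: 0.5 / v)


def sin(a):
    a = as_tensor(a)
    return _unary(a, np.sin(a.value), lambda: np.cos(a.value))


def cos(a):
    a = as_tensor(a)
    return _unary(a, np.cos(a.value), lambda: -np.sin(a.value))


def tanh(a):
    a = as_tensor(a)
    v = np.tanh(a.value)
    return _unary(a, v, lambda: 1.0 - v ** 2)


def sigmoid(a):
    from scipy.special import expit
    a = as_tensor(a)
    v = expit(a.value)  # overflow-safe logistic
    return _unary(a, v, lambda: v * (1.0 - v))


def softplus(a):
    from scipy.special import expit
    a = as_tensor(a)
    v = np.logaddexp(0.0, a.value)
    return _unary(a, v, lambda: expit(a.value))


# ---------------------------------------------------------------------------
# complex structure
# ---------------------------------------------------------------------------

def abs2(a):
    """|a|² as a real tensor."""
    a = as_tensor(a)
    v = (a.value * np.conj(a.value)).real
    return _make(v, [(a, lambda g: 2.0 * g * a.value)])


def real(a):
    a = as_tensor(a)
    return _make(a.value.real.copy(), [(a, lambda g: g.astype(np.complex128)
                                        if _is_complex(a.value) else g)])


def imag(a):
    a = as_tensor(a)
    return _make(a.value.imag.copy(), [(a, lambda g: 1j * g)])


def conj(a):
    a = as_tensor(a)
    return _make(np.conj(a.value), [(a, lambda g: np.conj(g))])


# ---------------------------------------------------------------------------
# reductions, selection
# ---------------------------------------------------------------------------

def tsum(a, axis=None):
    a = as_tensor(a)
    v = a.value.sum(axis=axis)
    def vjp(g):
        if axis is None:
            return np.broadcast_to(g, a.value.shape)
        return np.broadcast_to(np.expand_dims(g, axis), a.value.shape)
    return _make(v, [(a, vjp)])


def tmean(a, axis=None):
    a = as_tensor(a)
    n = a.value.size if axis is None else a.value.shape[axis]
    return tsum(a, axis=axis) * (1.0 / n)


def tmax(a):
    """Max of a real tensor; subgradient routed to the first argmax pixel."""
    a = as_tensor(a)
    idx = np.unravel_index(np.argmax(a.value), a.value.shape)
    v = a.value[idx]
    def vjp(g):
        out = np.zeros_like(a.value)
        out[idx] = g
        return out
    return _make(np.asarray(v), [(a, vjp)])


def greater(a, b) -> np.ndarray:
    """Detached elementwise comparison (boolean mask, no gradient)."""
    av = a.value if isinstance(a, Tensor) else np.asarray(a)
    bv = b.value if isinstance(b, Tensor) else np.asarray(b)
    return av > bv


def where(cond: np.ndarray, a, b):
    """Both-branch differentiable select with a detached condition."""
    a, b = as_tensor(a), as_tensor(b)
    cond = np.asarray(cond)
    v = np.where(cond, a.value, b.value)
    return _make(v, [(a, lambda g: _unbroadcast(np.where(cond, g, 0.0), a.value.shape)),
                     (b, lambda g: _unbroadcast(np.where(cond, 0.0, g), b.value.shape))])


def clip_min(a, lo: float):
    """max(a, lo) elementwise, subgradient passes where a > lo."""
    a = as_tensor(a)
    mask = a.value > lo
    v = np.where(mask, a.value, lo)
    return _make(v, [(a, lambda g: np.where(mask, g, 0.0))])


def logsumexp(a, scale: float = 1.0):
    """log(sum(exp(scale*a)))/scale, numerically stable, differentiable."""
    a = as_tensor(a)
    m = Tensor(np.max(scale * a.value))  # detached shift
    s = tsum(exp(a * scale - m))
    return (log(s) + m) * (1.0 / scale)


# ---------------------------------------------------------------------------
# structural ops
# ---------------------------------------------------------------------------

def getitem(a, idx):
    a = as_tensor(a)
    v = a.value[idx]
    def vjp(g):
        out = np.zeros(a.value.shape, dtype=g.dtype if _is_complex(g) or not _is_complex(a.value)
                       else np.complex128)
        if _is_complex(a.value) and not _is_complex(g):
            out = out.astype(np.complex128)
        np.add.at(out, idx, g)
        return out
    return _make(v, [(a, vjp)])


def reshape(a, shape):
    a = as_tensor(a)
    return _make(a.value.reshape(shape), [(a, lambda g: g.reshape(a.value.shape))])


def stack(ts, axis=0):
    ts = [as_tensor(t) for t in ts]
    v = np.stack([t.value for t in ts], axis=axis)
    parents = []
    for i, t in enumerate(ts):
        def vjp(g, i=i, t=t):
            return np.take(g, i, axis=axis)
        parents.append((t, vjp))
    return _make(v, parents)


def pad2(a, ny: int, nx: int):
    """Zero-pad a 2-D raster at the bottom/right to shape (ny, nx)."""
    a = as_tensor(a)
    h, w = a.value.shape
    v = np.zeros((ny, nx), dtype=np.complex128 if _is_complex(a.value) else a.value.dtype)
    v[:h, :w] = a.value
    return _make(v, [(a, lambda g: g[:h, :w])])


def crop2(a, ny: int, nx: int, oy: int = 0, ox: int = 0):
    a = as_tensor(a)
    v = a.value[oy:oy + ny, ox:ox + nx]
    def vjp(g):
        out = np.zeros(a.value.shape, dtype=g.dtype)
        out[oy:oy + ny, ox:ox + nx] = g
        return out
    return _make(v, [(a, vjp)])


# ---------------------------------------------------------------------------
# Fourier transforms (linear; adjoint = conjugate transpose)
# ---------------------------------------------------------------------------

def fft2(a):
    a = as_tensor(a)
    v = np.fft.fft2(a.value)
    n = v.size
    return _make(v, [(a, lambda g: np.fft.ifft2(g) * n)])


def ifft2(a):
    a = as_tensor(a)
    v = np.fft.ifft2(a.value)
    n = v.size
    return _make(v, [(a, lambda g: np.fft.fft2(g) / n)])


def fft(a, axis=-1):
    a = as_tensor(a)
    v = np.fft.fft(a.value, axis=axis)
    n = a.value.shape[axis]
    return _make(v, [(a, lambda g: np.fft.ifft(g, axis=axis) * n)])


def ifft(a, axis=-1):
    a = as_tensor(a)
    v = np.fft.ifft(a.value, axis=axis)
    n = a.value.shape[axis]
    return _make(v, [(a, lambda g: np.fft.fft(g, axis=axis) / n)])
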