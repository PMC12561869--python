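"""Minimal reverse-mode automatic differentiation on numpy arrays.

A tape-based tensor engine providing exactly the operations the sleep-staging
network needs: broadcast arithmetic, matrix products, the usual pointwise
nonlinearities, reductions, slicing/concatenation, strided 1-D convolution,
non-overlapping max pooling, and a fused softmax cross-entropy.  Gradients are
accumulated by topological traversal of the recorded graph.

Every operation is validated against central-difference numerical gradients in
the test suite; keep new primitives covered the same way.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add", "mul", "matmul", "concat", "sigmoid", "tanh", "leaky_relu",
    "relu", "exp", "log", "reduce_sum", "reduce_mean", "reshape",
    "transpose", "getitem", "sqrt", "power", "conv1d", "maxpool1d",
    "dropout", "softmax_cross_entropy", "softmax", "unbind_time",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    # -- graph traversal ---------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        """Accumulate gradients of ``self`` into every reachable leaf."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: LSTM graphs exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ----------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        """Wrap scalars at self's dtype so float32 graphs stay float32."""
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        return add(self, self._coerce(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, self._coerce(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, Tensor(np.asarray(-1.0, dtype=self.data.dtype)))

    def __sub__(self, other):
        return add(self, -self._coerce(other))

    def __rsub__(self, other):
        return add(self._coerce(other), -self)

    def __truediv__(self, other):
        return mul(self, power(self._coerce(other), -1.0))

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray, own: bool = False):
    """Add ``g`` into ``t.grad``.

    ``own=True`` promises that ``g`` is a freshly allocated array no other
    node holds, so it can be adopted without a defensive copy.
    """
    if not t.requires_grad:
        return
    if t.grad is None:
        if own and g.dtype == t.data.dtype:
            t.grad = g
        else:
            t.grad = g.astype(t.data.dtype, copy=True)
    else:
        t.grad += g


def _node(data, parents, backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=parents if req else (),
                  backward=backward if req else None)


# -- arithmetic ------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bw(g):
        ga = _unbroadcast(g, a.data.shape)
        _accum(a, ga, own=ga is not g)
        gb = _unbroadcast(g, b.data.shape)
        _accum(b, gb, own=gb is not g)

    return _node(out_data, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape), own=True)
        _accum(b, _unbroadcast(g * a.data, b.data.shape), own=True)

    return _node(out_data, (a, b), bw)


def power(a: Tensor, p: float) -> Tensor:
    out_data = a.data ** p

    def bw(g):
        _accum(a, g * p * a.data ** (p - 1.0), own=True)

    return _node(out_data, (a,), bw)


def sqrt(a: Tensor) -> Tensor:
    return power(a, 0.5)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product of 2-D operands (batched stacks flattened by callers)."""
    out_data = a.data @ b.data

    def bw(g):
        _accum(a, g @ b.data.swapaxes(-1, -2), own=True)
        _accum(b, a.data.swapaxes(-1, -2) @ g, own=True)

    return _node(out_data, (a, b), bw)


# -- pointwise nonlinearities ---------------------------------------------

def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def bw(g):
        _accum(a, g * out_data * (1.0 - out_data), own=True)

    return _node(out_data, (a,), bw)


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def bw(g):
        _accum(a, g * (1.0 - out_data * out_data), own=True)

    return _node(out_data, (a,), bw)


def leaky_relu(a: Tensor, slope: float = 0.01) -> Tensor:
    out_data = np.where(a.data > 0, a.data, slope * a.data)

    def bw(g):
        _accum(a, g * np.where(a.data > 0, 1.0, slope).astype(a.data.dtype), own=True)

    return _node(out_data, (a,), bw)


def relu(a: Tensor) -> Tensor:
    out_data = np.maximum(a.data, 0)

    def bw(g):
        _accum(a, g * (a.data > 0), own=True)

    return _node(out_data, (a,), bw)


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def bw(g):
        _accum(a, g * out_data, own=True)

    return _node(out_data, (a,), bw)


def log(a: Tensor) -> Tensor:
    out_data = np.log(a.data)

    def bw(g):
        _accum(a, g / a.data, own=True)

    return _node(out_data, (a,), bw)


# -- reductions / shape ----------------------------------------------------

def reduce_sum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape).copy(), own=True)
            return
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            g = np.expand_dims(g, axes)
        _accum(a, np.broadcast_to(g, a.data.shape).copy(), own=True)

    return _node(out_data, (a,), bw)


def reduce_mean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return reduce_sum(a, axis, keepdims) * (1.0 / float(n))


def reshape(a: Tensor, shape) -> Tensor:
    out_data = a.data.reshape(shape)

    def bw(g):
        _accum(a, g.reshape(a.data.shape))

    return _node(out_data, (a,), bw)


def transpose(a: Tensor, axes) -> Tensor:
    out_data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def bw(g):
        _accum(a, g.transpose(inv))

    return _node(out_data, (a,), bw)


def _is_basic_index(idx) -> bool:
    parts = idx if isinstance(idx, tuple) else (idx,)
    return all(isinstance(p, (int, np.integer, slice)) or p is Ellipsis
               for p in parts)


def getitem(a: Tensor, idx) -> Tensor:
    out_data = a.data[idx]

    def bw(g):
        full = np.zeros_like(a.data)
        if _is_basic_index(idx):  # slices never alias, plain assign is exact
            full[idx] = g
        else:
            np.add.at(full, idx, g)
        _accum(a, full, own=True)

    return _node(out_data, (a,), bw)


def concat(tensors, axis: int) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return _node(out_data, tuple(tensors), bw)


def unbind_time(x: Tensor) -> list[Tensor]:
    """Split a (B, T, D) tensor into T views of shape (B, D).

    Gradients from all slices are gathered into one shared buffer and flushed
    to ``x`` once the last slice has been processed, avoiding T full-size
    allocations.  Every returned slice must participate in the graph that
    ``backward()`` is called on (true for recurrent unrolling, the only
    caller); an unused slice would leave the buffer unflushed.
    """
    if not x.requires_grad:
        return [Tensor(x.data[:, t, :]) for t in range(x.shape[1])]
    T = x.shape[1]
    buf = np.zeros_like(x.data)
    pending = {"n": T}

    def make_bw(t):
        def bw(g):
            buf[:, t, :] += g
            pending["n"] -= 1
            if pending["n"] == 0:
                _accum(x, buf, own=True)
        return bw

    return [Tensor(x.data[:, t, :], requires_grad=True, parents=(x,),
                   backward=make_bw(t)) for t in range(T)]


# -- network primitives ----------------------------------------------------

def _im2col(x: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    """View of shape (B, C, L_out, K) over a (B, C, L) array."""
    B, C, L = x.shape
    L_out = (L - kernel) // stride + 1
    s0, s1, s2 = x.strides
    return np.lib.stride_tricks.as_strided(
        x, shape=(B, C, L_out, kernel), strides=(s0, s1, s2 * stride, s2),
        writeable=False)


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int) -> Tensor:
    """Strided valid cross-correlation: (B,C,L) * (F,C,K) -> (B,F,L_out)."""
    B, C, L = x.data.shape
    F, Cw, K = w.data.shape
    if C != Cw:
        raise ValueError(f"conv1d channel mismatch: input {C}, kernel {Cw}")
    if L < K:
        raise ValueError(f"conv1d input length {L} shorter than kernel {K}")
    patches = _im2col(x.data, K, stride)
    out_data = np.einsum("bclk,fck->bfl", patches, w.data, optimize=True)
    out_data += b.data[None, :, None]

    def bw(g):
        _accum(w, np.einsum("bfl,bclk->fck", g, patches, optimize=True), own=True)
        _accum(b, g.sum(axis=(0, 2)), own=True)
        if x.requires_grad:
            L_out = g.shape[2]
            gcol = np.einsum("bfl,fck->bclk", g, w.data, optimize=True)
            gx = np.zeros_like(x.data)
            for k in range(K):
                gx[:, :, k:k + L_out * stride:stride] += gcol[:, :, :, k]
            _accum(x, gx, own=True)

    return _node(out_data, (x, w, b), bw)


def maxpool1d(x: Tensor, pool: int) -> Tensor:
    """Non-overlapping max pooling along time; trailing remainder dropped."""
    B, F, L = x.data.shape
    L_out = L // pool
    xv = x.data[:, :, :L_out * pool].reshape(B, F, L_out, pool)
    arg = xv.argmax(axis=3)
    out_data = np.take_along_axis(xv, arg[..., None], axis=3)[..., 0]

    def bw(g):
        gx = np.zeros((B, F, L_out, pool), dtype=x.data.dtype)
        np.put_along_axis(gx, arg[..., None], g[..., None], axis=3)
        full = np.zeros_like(x.data)
        full[:, :, :L_out * pool] = gx.reshape(B, F, L_out * pool)
        _accum(x, full)

    return _node(out_data, (x,), bw)


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout: identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    return mul(x, Tensor(mask))


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax on plain arrays (inference path)."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray,
                          class_weights: np.ndarray | None = None) -> Tensor:
    """Mean cross-entropy from raw logits (log-sum-exp form).

    ``labels`` are integer class indices.  With ``class_weights`` each
    sample's loss term is multiplied by the weight of its true class.
    """
    labels = np.asarray(labels)
    B = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    logp = z - lse[:, None]
    wvec = (np.ones(B, dtype=logits.data.dtype) if class_weights is None
            else np.asarray(class_weights, dtype=logits.data.dtype)[labels])
    nll = -logp[np.arange(B), labels] * wvec
    out_data = np.asarray(nll.mean(), dtype=logits.data.dtype)

    def bw(g):
        probs = np.exp(logp)
        probs[np.arange(B), labels] -= 1.0
        _accum(logits, g * probs * wvec[:, None] / B, own=True)

    return _node(out_data, (logits,), bw)
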