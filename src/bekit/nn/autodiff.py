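"""A small reverse-mode automatic-differentiation engine over numpy arrays.

Only the operations needed by the attention encoders are implemented: basic
arithmetic with broadcasting, (batched) matmul, reductions, softmax, layer
normalization, embedding lookup, dropout and two fused losses.  Gradients are
accumulated by topological-order backward passes; every op's backward is
checked against finite differences in the test suite.

Computation runs in float32 by default (the sequences are 20-34 tokens and the
heads are scalar, so single precision is ample and roughly twice as fast on
CPU); :func:`set_default_dtype` switches to float64 for tight finite-difference
gradient checks.  Checkpoints round-trip bit-identically in either precision.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    """Set the floating dtype used by newly created tensors (float32/float64)."""
    global DTYPE
    DTYPE = np.dtype(dtype).type


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    # -- graph walking --------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            if t._backward is not None:
                t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        if not self.requires_grad:
            return
        g = _unbroadcast(np.asarray(grad), self.data.shape)
        if self.grad is None:
            # own the buffer: g may alias the child's grad array
            self.grad = g.copy() if g is grad else g
        else:
            self.grad += g

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, (self, other))
        out._backward = lambda g: (self._accum(g), other._accum(g))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, (self, other))
        out._backward = lambda g: (self._accum(g * other.data),
                                   other._accum(g * self.data))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data / other.data, (self, other))
        out._backward = lambda g: (
            self._accum(g / other.data),
            other._accum(-g * self.data / (other.data ** 2)),
        )
        return out

    def __pow__(self, n: float):
        out = Tensor(self.data ** n, (self,))
        out._backward = lambda g: self._accum(g * n * self.data ** (n - 1))
        return out

    def __matmul__(self, other):
        out = Tensor(self.data @ other.data, (self, other))

        def bwd(g):
            self._accum(g @ np.swapaxes(other.data, -1, -2))
            other._accum(np.swapaxes(self.data, -1, -2) @ g)

        out._backward = bwd
        return out

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), (self,))
        out._backward = lambda g: self._accum(g.transpose(*inv))
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities --------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), (self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, (self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, (self,))
        out._backward = lambda g: self._accum(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, (self,))
        out._backward = lambda g: self._accum(
            s * (g - (g * s).sum(axis=axis, keepdims=True))
        )
        return out


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=DTYPE), requires_grad=True)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with learned affine parameters."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(gamma.data * xhat + beta.data, (x, gamma, beta))
    d = x.data.shape[-1]

    def bwd(g):
        gamma._accum((g * xhat).sum(axis=tuple(range(g.ndim - 1))))
        beta._accum(g.sum(axis=tuple(range(g.ndim - 1))))
        gx = g * gamma.data
        x._accum(inv * (gx - gx.mean(axis=-1, keepdims=True)
                        - xhat * (gx * xhat).mean(axis=-1, keepdims=True)))

    out._backward = bwd
    return out


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``weight[ids]`` with scatter-add backward."""
    ids = np.asarray(ids)
    out = Tensor(weight.data[ids], (weight,))

    def bwd(g):
        if weight.requires_grad:
            gw = np.zeros_like(weight.data)
            np.add.at(gw, ids.reshape(-1), g.reshape(-1, weight.data.shape[-1]))
            if weight.grad is None:
                weight.grad = gw
            else:
                weight.grad += gw

    out._backward = bwd
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator | None, train: bool) -> Tensor:
    if not train or p <= 0 or rng is None:
        return x
    mask = (rng.random(x.data.shape, dtype=np.float32) >= p).astype(x.data.dtype)
    mask /= (1.0 - p)
    out = Tensor(x.data * mask, (x,))
    out._backward = lambda g: x._accum(g * mask)
    return out


def concat(tensors, axis=-1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = bwd
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray,
                    weights: np.ndarray | None = None) -> Tensor:
    """Weighted-mean binary cross-entropy against soft labels, from logits."""
    z = logits.data
    y = np.asarray(targets, dtype=DTYPE)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=DTYPE)
    ll = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    wsum = w.sum()
    out = Tensor((w * ll).sum() / wsum, (logits,))
    sig = 1.0 / (1.0 + np.exp(-z))
    out._backward = lambda g: logits._accum(g * w * (sig - y) / wsum)
    return out


def segment_softmax_xent(scores: Tensor, targets: np.ndarray,
                         segment_ids: np.ndarray,
                         segment_weights: np.ndarray | None = None) -> Tensor:
    """Cross-entropy between per-segment softmax of ``scores`` and ``targets``.

    ``segment_ids`` must be sorted, labelling contiguous groups 0..S-1 (one
    group per site); ``targets`` sum to 1 within each group.  The per-group
    losses are combined as a weighted mean.
    """
    z = scores.data
    seg = np.asarray(segment_ids)
    t = np.asarray(targets, dtype=DTYPE)
    n_seg = int(seg[-1]) + 1 if len(seg) else 0
    w = np.ones(n_seg) if segment_weights is None else np.asarray(segment_weights, float)

    zmax = np.full(n_seg, -np.inf)
    np.maximum.at(zmax, seg, z)
    e = np.exp(z - zmax[seg])
    denom = np.bincount(seg, weights=e, minlength=n_seg)
    logp = (z - zmax[seg]) - np.log(denom)[seg]
    p = e / denom[seg]
    wsum = w.sum()
    loss = -(w[seg] * t * logp).sum() / wsum
    tsum = np.bincount(seg, weights=t, minlength=n_seg)
    out = Tensor(loss, (scores,))
    out._backward = lambda g: scores._accum(g * w[seg] * (p * tsum[seg] - t) / wsum)
    return out


class AdamW:
    """AdamW optimizer with decoupled weight decay."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = params
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None
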