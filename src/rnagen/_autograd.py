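"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the primitives the toolkit's neural models need:
broadcast-aware arithmetic, batched matmul, gather (fancy indexing, used
for embeddings and graph neighborhoods), softmax, and a fused
masked/label-smoothed cross entropy. Gradients are accumulated in float32.

This is deliberately small: a handful of operations with hand-written
adjoints, checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "cat", "masked_cross_entropy", "AdamW"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array plus a gradient and the closure that backpropagates it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        # no defensive copy: ops that would hand the same buffer to two
        # tensors (only __add__) copy there; disjoint views are safe
        if self.grad is None:
            if g.dtype == np.float32:
                self.grad = g
            else:
                self.grad = g.astype(np.float32)
        else:
            self.grad += g

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            handed = False
            if self.requires_grad:
                ga = _unbroadcast(g, self.shape)
                handed = ga is g
                self._accum(ga)
            if other.requires_grad:
                gb = _unbroadcast(g, other.shape)
                if gb is g and handed:
                    gb = g.copy()  # avoid two tensors sharing one grad buffer
                other._accum(gb)

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other ** -1.0

    def __pow__(self, p: float):
        # integer/half exponents hit slow libm paths on float32; special-case
        if p == -0.5:
            out_data = 1.0 / np.sqrt(self.data)
        elif p == -1.0:
            out_data = 1.0 / self.data
        elif p == 2.0:
            out_data = self.data * self.data
        else:
            out_data = self.data ** np.float32(p)

        def backward(g):
            if p == 2.0:
                self._accum(g * (2.0 * self.data))
            else:
                # p * x^(p-1) == p * out / x (x != 0 for the fractional cases)
                self._accum(g * np.float32(p) * out_data / self.data)

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return self._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), backward)

    def gelu(self):
        # tanh approximation, matching the usual transformer implementation
        x = self.data
        c = np.float32(np.sqrt(2.0 / np.pi))
        x2 = x * x
        inner = c * (x + np.float32(0.044715) * x2 * x)
        t = np.tanh(inner)
        out_data = np.float32(0.5) * x * (1.0 + t)

        def backward(g):
            dt = (1.0 - t * t) * c * (1.0 + np.float32(3 * 0.044715) * x2)
            self._accum(g * (np.float32(0.5) * (1.0 + t) + np.float32(0.5) * x * dt))

        return self._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            self._accum(y * (g - dot))

        return self._make(y, (self,), backward)

    # -- reductions and shape ops ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).astype(np.float32))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).astype(np.float32))

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.shape

        def backward(g):
            self._accum(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def swapaxes(self, a: int, b: int):
        def backward(g):
            self._accum(np.swapaxes(g, a, b))

        return self._make(np.swapaxes(self.data, a, b), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(
            isinstance(p, (slice, int)) or p is Ellipsis or p is None for p in parts
        )

        def backward(g):
            full = np.zeros_like(self.data)
            if basic:
                full[idx] += g  # basic indices never alias; fast path
            else:
                np.add.at(full, idx, g)
            self._accum(full)

        return self._make(out_data, (self,), backward)

    # -- autodiff driver --------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # free the graph
        for node in topo:
            node._backward = None
            node._parents = ()


def cat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate along `axis`, splitting the gradient back."""
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(t for t in tensors if t.requires_grad)

        def backward(g):
            pieces = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
            for t, piece in zip(tensors, pieces):
                if t.requires_grad:
                    t._accum(piece)

        out._backward = backward
    return out


def masked_cross_entropy(
    logits: Tensor,
    targets: np.ndarray,
    mask: np.ndarray,
    label_smoothing: float = 0.0,
) -> Tensor:
    """Mean cross entropy over positions where mask is true.

    logits: (N, V); targets: (N,) int; mask: (N,) bool. Smoothing spreads
    `label_smoothing` of the target mass uniformly over the vocabulary.
    """
    n, v = logits.data.shape
    mask = np.asarray(mask, dtype=bool)
    denom = max(int(mask.sum()), 1)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - logsumexp
    eps = float(label_smoothing)
    tgt_logp = logp[np.arange(n), targets]
    if eps > 0.0:
        nll = -((1.0 - eps) * tgt_logp + eps * logp.mean(axis=-1))
    else:
        nll = -tgt_logp
    loss_val = float(nll[mask].sum() / denom)

    out = Tensor(np.float32(loss_val))
    if logits.requires_grad:
        out.requires_grad = True
        out._parents = (logits,)

        def backward(g):
            p = np.exp(logp)
            target_dist = np.full((n, v), eps / v, dtype=np.float32)
            target_dist[np.arange(n), targets] += 1.0 - eps
            grad = (p - target_dist) * mask[:, None] / denom
            logits._accum(grad * g)

        out._backward = backward
    return out


class AdamW:
    """AdamW with decoupled weight decay over a dict of parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1.0 - b1) * g
            self.v[k] = b2 * self.v[k] + (1.0 - b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
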