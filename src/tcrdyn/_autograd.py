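"""Compact tape-based reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations a small BERT-style encoder needs: broadcast
add/multiply, (batched) matmul, reshape/transpose, embedding gather, layer
normalization, GELU, softmax, dropout, and fused token/binary cross-entropy
losses.  Gradients are accumulated in float32 and are gradient-checked against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_diff = grad.ndim - len(shape)
    if ndim_diff > 0:
        grad = grad.sum(axis=tuple(range(ndim_diff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        """Reverse-accumulate d(self)/d(leaf) for all reachable leaves."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray):
        grad = grad.astype(DTYPE, copy=False)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad


def _binary(a: Tensor, b: Tensor, out_data, da, db) -> Tensor:
    def backward(grad):
        if a.requires_grad:
            a._accumulate(_unbroadcast(da(grad), a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(db(grad), b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    return _binary(a, b, a.data + b.data, lambda g: g, lambda g: g)


def mul(a: Tensor, b: Tensor) -> Tensor:
    return _binary(a, b, a.data * b.data, lambda g: g * b.data, lambda g: g * a.data)


def scale(a: Tensor, s: float) -> Tensor:
    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad * s)

    return Tensor(a.data * s, parents=(a,), backward=backward)


def add_const(a: Tensor, c) -> Tensor:
    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad)

    return Tensor(a.data + np.asarray(c, dtype=DTYPE), parents=(a,), backward=backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = np.matmul(a.data, b.data)

    def backward(grad):
        if a.requires_grad:
            ga = np.matmul(grad, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), grad)
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return Tensor(out, parents=(a, b), backward=backward)


def reshape(a: Tensor, shape) -> Tensor:
    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad.reshape(a.data.shape))

    return Tensor(a.data.reshape(shape), parents=(a,), backward=backward)


def transpose(a: Tensor, axes) -> Tensor:
    inverse = np.argsort(axes)

    def backward(grad):
        if a.requires_grad:
            a._accumulate(np.transpose(grad, inverse))

    return Tensor(np.transpose(a.data, axes), parents=(a,), backward=backward)


def embedding(table: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather ``table[idx]`` with scatter-add backward."""
    out = table.data[idx]

    def backward(grad):
        if table.requires_grad:
            g = np.zeros_like(table.data)
            np.add.at(g, idx, grad)
            table._accumulate(g)

    return Tensor(out, parents=(table,), backward=backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = xhat * gamma.data + beta.data
    n = x.data.shape[-1]

    def backward(grad):
        if gamma.requires_grad:
            gamma._accumulate(_unbroadcast(grad * xhat, gamma.data.shape))
        if beta.requires_grad:
            beta._accumulate(_unbroadcast(grad, beta.data.shape))
        if x.requires_grad:
            gx_hat = grad * gamma.data
            gx = inv / n * (
                n * gx_hat
                - gx_hat.sum(axis=-1, keepdims=True)
                - xhat * (gx_hat * xhat).sum(axis=-1, keepdims=True)
            )
            x._accumulate(gx)

    return Tensor(out, parents=(x, gamma, beta), backward=backward)


_SQRT_2_OVER_PI = np.sqrt(2.0 / np.pi).astype(DTYPE)


def gelu(x: Tensor) -> Tensor:
    """GELU with the tanh approximation (the BERT convention)."""
    x3 = x.data**3
    inner = _SQRT_2_OVER_PI * (x.data + 0.044715 * x3)
    t = np.tanh(inner)
    out = 0.5 * x.data * (1.0 + t)

    def backward(grad):
        if x.requires_grad:
            dinner = _SQRT_2_OVER_PI * (1.0 + 3 * 0.044715 * x.data**2)
            dt = (1.0 - t**2) * dinner
            gx = 0.5 * (1.0 + t) + 0.5 * x.data * dt
            x._accumulate(grad * gx)

    return Tensor(out, parents=(x,), backward=backward)


def softmax_last(x: Tensor) -> Tensor:
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)

    def backward(grad):
        if x.requires_grad:
            dot = (grad * p).sum(axis=-1, keepdims=True)
            x._accumulate(p * (grad - dot))

    return Tensor(p, parents=(x,), backward=backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when ``rng`` is None (evaluation mode)."""
    if rng is None or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(DTYPE) / (1.0 - p)

    def backward(grad):
        if x.requires_grad:
            x._accumulate(grad * keep)

    return Tensor(x.data * keep, parents=(x,), backward=backward)


def token_cross_entropy(logits: Tensor, targets: np.ndarray, ignore_index: int = -100) -> Tensor:
    """Mean cross-entropy (nats) of ``logits`` (..., V) at positions where
    ``targets`` != ``ignore_index``.  Returns loss 0 if nothing is selected."""
    sel = targets != ignore_index
    n_sel = int(sel.sum())
    if n_sel == 0:
        return Tensor(0.0)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - logsumexp
    tgt = np.where(sel, targets, 0)
    picked = np.take_along_axis(logp, tgt[..., None], axis=-1)[..., 0]
    loss = -(picked * sel).sum() / n_sel

    def backward(grad):
        if logits.requires_grad:
            p = np.exp(logp)
            onehot = np.zeros_like(p)
            np.put_along_axis(onehot, tgt[..., None], 1.0, axis=-1)
            g = (p - onehot) * sel[..., None] / n_sel
            logits._accumulate(grad * g)

    return Tensor(loss, parents=(logits,), backward=backward)


def binary_cross_entropy_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean BCE (nats) from raw logits; numerically stable log1p form."""
    z = logits.data
    y = labels.astype(DTYPE)
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))

    def backward(grad):
        if logits.requires_grad:
            sig = 1.0 / (1.0 + np.exp(-z))
            logits._accumulate(grad * (sig - y) / z.size)

    return Tensor(loss, parents=(logits,), backward=backward)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))
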