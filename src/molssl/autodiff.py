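"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package's whole learning stack (GIN message passing, projection heads,
classification and contrastive losses, Adam) runs on this engine.  It
implements exactly the operations the model needs: dense affine maps, ReLU,
row gather / segment reduction for graph batching, and the loss heads.
Tensors hold float64 data; ``backward()`` on a scalar loss accumulates
gradients into every reachable tensor via topological traversal.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            stack = [(t, iter(t._parents))]
            if id(t) in seen:
                return
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None


def param(data, rng: np.random.Generator | None = None, scale: float | None = None,
          shape=None) -> Tensor:
    """A trainable leaf tensor; with rng/shape given, He-style normal init."""
    if shape is not None:
        fan_in = shape[0] if len(shape) > 1 else shape[0]
        s = scale if scale is not None else np.sqrt(2.0 / fan_in)
        data = rng.normal(0.0, s, size=shape)
    return Tensor(data, requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to the operand's shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def bw(g):
        if a.grad is not None:
            a.grad += _unbroadcast(g, a.data.shape)
        if b.grad is not None:
            b.grad += _unbroadcast(g, b.data.shape)
    out._backward = bw
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, parents=(a, b))

    def bw(g):
        if a.grad is not None:
            a.grad += g @ b.data.T
        if b.grad is not None:
            b.grad += a.data.T @ g
    out._backward = bw
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(np.where(mask, a.data, 0.0), parents=(a,))

    def bw(g):
        if a.grad is not None:
            a.grad += g * mask
    out._backward = bw
    return out


def gather(a: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows ``a[idx]``; backward scatter-adds into the source rows."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(a.data[idx], parents=(a,))

    def bw(g):
        if a.grad is not None:
            np.add.at(a.grad, idx, g)
    out._backward = bw
    return out


def segment_sum(a: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``a`` into ``num_segments`` buckets given per-row ids."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    data = np.zeros((num_segments, a.data.shape[1]), dtype=np.float64)
    np.add.at(data, segment_ids, a.data)
    out = Tensor(data, parents=(a,))

    def bw(g):
        if a.grad is not None:
            a.grad += g[segment_ids]
    out._backward = bw
    return out


def segment_mean(a: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    counts = np.bincount(segment_ids, minlength=num_segments).astype(np.float64)
    counts = np.maximum(counts, 1.0)
    data = np.zeros((num_segments, a.data.shape[1]), dtype=np.float64)
    np.add.at(data, segment_ids, a.data)
    data /= counts[:, None]
    out = Tensor(data, parents=(a,))

    def bw(g):
        if a.grad is not None:
            a.grad += (g / counts[:, None])[segment_ids]
    out._backward = bw
    return out


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    return add(matmul(x, w), b)


def scale(a: Tensor, s: float) -> Tensor:
    out = Tensor(a.data * s, parents=(a,))

    def bw(g):
        if a.grad is not None:
            a.grad += g * s
    out._backward = bw
    return out


# -- loss heads ---------------------------------------------------------------

def cross_entropy_mean(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy of integer labels over the batch."""
    labels = np.asarray(labels, dtype=np.intp)
    n, c = logits.data.shape
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError("label out of range for logit width")
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    expz = np.exp(z)
    probs = expz / expz.sum(axis=1, keepdims=True)
    nll = -np.log(probs[np.arange(n), labels] + 1e-300)
    out = Tensor(nll.mean(), parents=(logits,))

    def bw(g):
        if logits.grad is not None:
            grad = probs.copy()
            grad[np.arange(n), labels] -= 1.0
            logits.grad += g * grad / n
    out._backward = bw
    return out


def bce_with_logits_mean(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on a column of logits with {0,1} targets."""
    y = np.asarray(targets, dtype=np.float64).reshape(-1)
    x = logits.data.reshape(-1)
    n = x.size
    # log(1+e^x) computed stably
    loss = np.mean(np.maximum(x, 0) - x * y + np.log1p(np.exp(-np.abs(x))))
    out = Tensor(loss, parents=(logits,))

    def bw(g):
        if logits.grad is not None:
            p = 1.0 / (1.0 + np.exp(-x))
            logits.grad += (g * (p - y) / n).reshape(logits.data.shape)
    out._backward = bw
    return out


def mse_mean(pred: Tensor, targets: np.ndarray) -> Tensor:
    y = np.asarray(targets, dtype=np.float64).reshape(pred.data.shape)
    diff = pred.data - y
    out = Tensor(np.mean(diff ** 2), parents=(pred,))

    def bw(g):
        if pred.grad is not None:
            pred.grad += g * 2.0 * diff / diff.size
    out._backward = bw
    return out


def pairwise_l2_mean(a: Tensor, b: Tensor, squared: bool = False) -> Tensor:
    """Mean over rows of the Euclidean distance ||a_i - b_i||_2.

    With ``squared=True`` the squared distance is averaged instead.  The
    gradient of the plain distance at coincident points is defined as 0.
    """
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch {a.data.shape} vs {b.data.shape}")
    diff = a.data - b.data
    sq = np.sum(diff ** 2, axis=1)
    n = sq.shape[0]
    if squared:
        out = Tensor(sq.mean(), parents=(a, b))

        def bw(g):
            grad = g * 2.0 * diff / n
            if a.grad is not None:
                a.grad += grad
            if b.grad is not None:
                b.grad -= grad
    else:
        dist = np.sqrt(sq)
        out = Tensor(dist.mean(), parents=(a, b))

        def bw(g):
            safe = np.where(dist > 0, dist, 1.0)
            grad = g * diff / (safe[:, None] * n)
            grad[dist == 0] = 0.0
            if a.grad is not None:
                a.grad += grad
            if b.grad is not None:
                b.grad -= grad
    out._backward = bw
    return out


# -- optimizer ----------------------------------------------------------------

class Adam:
    """Adam optimizer over a dict of named parameter tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()
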