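"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the encoder needs: broadcasted arithmetic,
batched matmul, embedding lookup, layer norm, GELU, softmax, rotary position
application, row gathering, and a fused masked cross-entropy. Gradients are
accumulated on every tensor in the graph, which lets attribution code read
d(logit)/d(hidden state) at intermediate layers after a single backward.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "cross_entropy_logits"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_prev", "_backward", "name")

    def __init__(self, data, _prev=(), _backward=None, name=""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self._prev = _prev
        self._backward = _backward
        self.name = name

    # ------------------------------------------------------------------ util
    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        self.grad = g if self.grad is None else self.grad + g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar root")
        topo, seen = [], set()
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
            for child in node._prev:
                stack.append((child, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def bwd(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            out = Tensor(self.data * other, (self,))
            out._backward = lambda g: self._accum(g * other)
            return out
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-other if isinstance(other, Tensor) else Tensor(-np.asarray(other)))

    def __matmul__(self, other):
        out = Tensor(self.data @ other.data, (self, other))

        def bwd(g):
            self._accum(
                _unbroadcast(g @ other.data.swapaxes(-1, -2), self.data.shape)
            )
            other._accum(
                _unbroadcast(self.data.swapaxes(-1, -2) @ g, other.data.shape)
            )

        out._backward = bwd
        return out

    def add_const(self, arr: np.ndarray):
        """Add a non-differentiable array (e.g. an attention bias)."""
        out = Tensor(self.data + arr, (self,))
        out._backward = lambda g: self._accum(_unbroadcast(g, self.data.shape))
        return out

    # --------------------------------------------------------------- shaping
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def swapaxes(self, a, b):
        out = Tensor(self.data.swapaxes(a, b), (self,))
        out._backward = lambda g: self._accum(g.swapaxes(a, b))
        return out

    def take_position(self, index: int, axis: int = 1):
        """Select one position along ``axis`` (e.g. the <cls> column)."""
        out = Tensor(np.take(self.data, index, axis=axis), (self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            sl = [slice(None)] * self.data.ndim
            sl[axis] = index
            full[tuple(sl)] = g
            self._accum(full)

        out._backward = bwd
        return out

    def gather_rows(self, rows: np.ndarray):
        """Select rows of a 2-D tensor (used to keep only loss positions)."""
        out = Tensor(self.data[rows], (self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, rows, g)
            self._accum(full)

        out._backward = bwd
        return out

    # ------------------------------------------------------------ activations
    def gelu(self):
        x = self.data
        c = np.float32(np.sqrt(2.0 / np.pi))
        x2 = x * x
        t = np.tanh(c * (x + np.float32(0.044715) * x2 * x))
        out = Tensor(np.float32(0.5) * x * (np.float32(1.0) + t), (self,))

        def bwd(g):
            dinner = c * (np.float32(1.0) + np.float32(3 * 0.044715) * x2)
            deriv = np.float32(0.5) * (np.float32(1.0) + t) \
                + np.float32(0.5) * x * (np.float32(1.0) - t * t) * dinner
            self._accum(g * deriv)

        out._backward = bwd
        return out

    def softmax_last(self):
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        out = Tensor(p, (self,))

        def bwd(g):
            dot = (g * p).sum(axis=-1, keepdims=True)
            self._accum(p * (g - dot))

        out._backward = bwd
        return out

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out = Tensor(xhat * gamma.data + beta.data, (self, gamma, beta))
        n = x.shape[-1]

        def bwd(g):
            gamma._accum(_unbroadcast(g * xhat, gamma.data.shape))
            beta._accum(_unbroadcast(g, beta.data.shape))
            gx = g * gamma.data
            dx = (
                gx - gx.mean(axis=-1, keepdims=True)
                - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            ) * inv
            self._accum(dx.astype(np.float32))
            del dx

        out._backward = bwd
        return out

    def rotary(self, cos: np.ndarray, sin: np.ndarray):
        """Apply rotary position encoding along the last (head) dimension.

        ``cos``/``sin`` have shape (L, dh) and broadcast over (B, H, L, dh);
        rotate_half splits the head dimension into two halves.
        """
        x = self.data
        h = x.shape[-1] // 2
        x1, x2 = x[..., :h], x[..., h:]
        rot = np.concatenate([-x2, x1], axis=-1)
        out = Tensor(x * cos + rot * sin, (self,))

        def bwd(g):
            gs = g * sin
            g1, g2 = gs[..., :h], gs[..., h:]
            rot_t = np.concatenate([g2, -g1], axis=-1)
            self._accum(g * cos + rot_t)

        out._backward = bwd
        return out

    @staticmethod
    def embedding(weight: "Tensor", ids: np.ndarray):
        out = Tensor(weight.data[ids], (weight,))

        def bwd(g):
            full = np.zeros_like(weight.data)
            np.add.at(full, ids, g)
            weight._accum(full)

        out._backward = bwd
        return out


def cross_entropy_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of a (N, V) logit tensor against integer targets.

    Callers are expected to pre-filter to loss-bearing rows (no ignore
    handling here); the backward pass is the fused softmax-minus-onehot.
    """
    if logits.data.ndim != 2 or len(targets) != logits.data.shape[0]:
        raise ValueError("logits must be (N, V) aligned with targets")
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1))
    nll = logsumexp - z[np.arange(n), targets]
    out = Tensor(np.float32(nll.mean()), (logits,))

    def bwd(g):
        p = np.exp(z - logsumexp[:, None])
        p[np.arange(n), targets] -= 1.0
        logits._accum((float(g) / n) * p)

    out._backward = bwd
    return out
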