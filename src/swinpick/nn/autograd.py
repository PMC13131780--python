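"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operator set needed by the 3D Swin U-Net: broadcasted
arithmetic, (batched) matrix products, shape manipulation (reshape, transpose,
roll, basic indexing), softmax, layer normalization, GELU, table gather for
relative position biases, dropout, and a fused weighted cross-entropy.

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`,
which topologically sorts the recorded graph.  All arrays are float32 unless
the caller supplies something else; integer index arrays never require grad.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra > 0:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32) if not isinstance(data, np.ndarray) else data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float32))

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            )

        return self._make(out_data, (self, other), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return self._make(out_data, (self, other), backward)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src_shape = self.data.shape
        return self._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(src_shape),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return self._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def roll(self, shift, axis):
        neg = tuple(-s for s in shift) if isinstance(shift, tuple) else -shift
        return self._make(
            np.roll(self.data, shift, axis=axis),
            (self,),
            lambda g: (np.roll(g, neg, axis=axis),),
        )

    def __getitem__(self, idx):
        src_shape = self.data.shape
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros(src_shape, dtype=g.dtype)
            full[idx] = g
            return (full,)

        return self._make(out_data, (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        src_shape = self.data.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, src_shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, src_shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities ------------------------------------------------------
    def softmax(self, axis=-1):
        x = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(x)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            return (y * (g - dot),)

        return self._make(y, (self,), backward)

    def gelu(self):
        from scipy.special import erf

        x = self.data
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0, dtype=np.float32)))
        y = x * cdf

        def backward(g):
            pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
            return (g * (cdf + x * pdf).astype(np.float32),)

        return self._make(y.astype(np.float32), (self,), backward)

    def layer_norm(self, weight: "Tensor", bias: "Tensor", eps: float = 1e-5):
        """Normalize over the last axis, then scale/shift."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        y = xhat * weight.data + bias.data
        n = x.shape[-1]

        def backward(g):
            gw = _unbroadcast(g * xhat, weight.data.shape)
            gb = _unbroadcast(g, bias.data.shape)
            gx_hat = g * weight.data
            gx = inv / n * (
                n * gx_hat
                - gx_hat.sum(axis=-1, keepdims=True)
                - xhat * (gx_hat * xhat).sum(axis=-1, keepdims=True)
            )
            return (gx.astype(np.float32), gw, gb)

        return self._make(y.astype(np.float32), (self, weight, bias), backward)

    def gather(self, index: np.ndarray):
        """Index the leading axis with an integer array (embedding lookup)."""
        index = np.asarray(index)
        src_shape = self.data.shape
        out_data = self.data[index]

        def backward(g):
            full = np.zeros(src_shape, dtype=g.dtype)
            np.add.at(full, index.reshape(-1), g.reshape((-1,) + src_shape[1:]))
            return (full,)

        return self._make(out_data, (self,), backward)

    def dropout(self, rate: float, rng: np.random.Generator):
        if rate <= 0.0:
            return self
        keep = (rng.random(self.data.shape) >= rate).astype(np.float32) / (1.0 - rate)
        return self * Tensor(keep)

    # -- losses --------------------------------------------------------------
    def cross_entropy(self, labels: np.ndarray, class_weights: np.ndarray):
        """Mean class-weighted cross-entropy.

        ``self`` holds logits of shape (N, K); ``labels`` is (N,) int;
        ``class_weights`` is (K,).  Reduction is the mean over the N samples
        (voxels), each sample scaled by the weight of its true class.
        """
        z = self.data
        labels = np.asarray(labels).reshape(-1)
        n, k = z.shape
        zmax = z.max(axis=1, keepdims=True)
        logsumexp = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
        logp_true = z[np.arange(n), labels] - logsumexp
        w = np.asarray(class_weights, dtype=np.float64)[labels]
        loss = float(-(w * logp_true).sum() / n)

        def backward(g):
            p = np.exp(z - zmax)
            p /= p.sum(axis=1, keepdims=True)
            onehot = np.zeros_like(p)
            onehot[np.arange(n), labels] = 1.0
            gz = (p - onehot) * (w[:, None] / n) * g
            return (gz.astype(np.float32),)

        return self._make(np.float32(loss), (self,), backward)

    # -- backward pass -------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float32)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


class Parameter(Tensor):
    """Trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)
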