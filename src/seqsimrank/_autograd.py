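"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the small matching networks in this package:
dense layers, elementwise nonlinearities, softmax attention, recurrent
cells, and binary cross-entropy. Gradients propagate through a
topologically sorted tape; broadcasting is handled by summing gradient
axes back to the operand shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack_rows", "bce_loss", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum grad over axes that were broadcast to reach `shape`'s partner."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _node(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._node(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._node(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._node(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._node(out_data, (self, other), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 2:
                return (g @ b.T, np.outer(a, g))
            if a.ndim == 2 and b.ndim == 1:
                return (np.outer(g, b), a.T @ g)
            if a.ndim == 1 and b.ndim == 1:
                return (g * b, g * a)
            if a.ndim > 2 and b.ndim == 2:
                # batched activations @ shared weights: sum weight grad over batch
                ga = g @ b.T
                gb = a.reshape(-1, a.shape[-1]).T @ g.reshape(-1, g.shape[-1])
                return (ga, gb)
            return (g @ np.swapaxes(b, -1, -2), np.swapaxes(a, -1, -2) @ g)

        return self._node(out_data, (self, other), backward)

    # -- nonlinearities and reductions --------------------------------------

    def tanh(self):
        t = np.tanh(self.data)
        return self._node(t, (self,), lambda g: (g * (1 - t**2),))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        return self._node(s, (self,), lambda g: (g * s * (1 - s),))

    def relu(self):
        mask = self.data > 0
        return self._node(self.data * mask, (self,), lambda g: (g * mask,))

    def exp(self):
        e = np.exp(self.data)
        return self._node(e, (self,), lambda g: (g * e,))

    def log(self):
        return self._node(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._node(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int):
        out_data = self.data.max(axis=axis)
        mask = self.data == np.expand_dims(out_data, axis)
        # split ties evenly so the gradient stays well-defined
        mask = mask / mask.sum(axis=axis, keepdims=True)

        def backward(g):
            return (np.expand_dims(g, axis) * mask,)

        return self._node(out_data, (self,), backward)

    def pow(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1),)

        return self._node(out_data, (self,), backward)

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return (s * (g - dot),)

        return self._node(s, (self,), backward)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        return self._node(out_data, (self,), lambda g: (g.reshape(self.shape),))

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return self._node(out_data, (self,), backward)

    # -- backward pass -------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, visited = [], set()

        def visit(node: "Tensor"):
            if id(node) in visited or not node.requires_grad:
                return
            visited.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if parent.requires_grad:
                    if parent.grad is None:
                        parent.grad = np.zeros_like(parent.data)
                    parent.grad = parent.grad + g


def concat(tensors, axis=-1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out = Tensor(out_data, requires_grad=any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def stack_rows(tensors) -> Tensor:
    """Stack equal-shape tensors along a new leading axis."""
    out_data = np.stack([t.data for t in tensors])

    def backward(g):
        return tuple(g[i] for i in range(len(tensors)))

    out = Tensor(out_data, requires_grad=any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def bce_loss(prob: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy of predicted probabilities."""
    target = np.asarray(target, dtype=float)
    p = prob * (1 - 2 * eps) + eps  # keep log() finite
    loss = -(Tensor(target) * p.log() + Tensor(1.0 - target) * (1 - p).log())
    return loss.mean()


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-2, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
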