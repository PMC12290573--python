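"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for a small Transformer encoder: broadcast-aware
elementwise arithmetic, batched matmul, softmax with an additive mask,
layer normalization, pooling and concatenation.  Tensors record a tape of
parent links; ``backward`` runs a topological sweep accumulating gradients.

Deterministic by construction — every op is a pure numpy computation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "SGDMomentum"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction ----------------------------------------------
    @staticmethod
    def _make(data, parents, backward_fn):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward_fn
        return out

    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g, out: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g, out):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("only division by plain scalars is supported")
        return self * (1.0 / scalar)

    def matmul(self, other):
        other = self._lift(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g, out):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __matmul__ = matmul

    def swapaxes(self, ax1: int, ax2: int):
        out_data = np.swapaxes(self.data, ax1, ax2)
        return Tensor._make(
            out_data, (self,), lambda g, out: (np.swapaxes(g, ax1, ax2),)
        )

    def reshape(self, *shape):
        orig = self.shape
        return Tensor._make(
            self.data.reshape(*shape), (self,), lambda g, out: (g.reshape(orig),)
        )

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g, out: (g * mask,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._make(
            out_data, (self,), lambda g, out: (g * (1.0 - out.data**2),)
        )

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(
            out_data, (self,), lambda g, out: (g * out.data * (1.0 - out.data),)
        )

    def softmax(self, mask: np.ndarray | None = None):
        """Row softmax over the last axis with optional additive mask.

        Mask entries are 0 (keep) or -inf (forbid); -inf rows out exactly
        (exp(-inf) = 0) so masked positions carry exactly zero weight.  A
        fully masked row is an error (no admissible key).
        """
        z = self.data if mask is None else self.data + mask
        zmax = np.max(z, axis=-1, keepdims=True)
        if not np.all(np.isfinite(zmax)):
            raise ValueError("softmax row fully masked: no admissible key")
        ez = np.exp(z - zmax)
        out_data = ez / ez.sum(axis=-1, keepdims=True)

        def backward(g, out):
            a = out.data
            dot = np.sum(g * a, axis=-1, keepdims=True)
            return (a * (g - dot),)

        return Tensor._make(out_data, (self,), backward)

    def layer_norm(self, gain: "Tensor", bias: "Tensor", eps: float = 1e-6):
        """Normalize over the last axis, then scale and shift."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out_data = xhat * gain.data + bias.data
        n = self.data.shape[-1]

        def backward(g, out):
            g_gain = _unbroadcast(g * xhat, gain.shape)
            g_bias = _unbroadcast(g, bias.shape)
            gx_hat = g * gain.data
            gx = inv * (
                gx_hat
                - gx_hat.mean(axis=-1, keepdims=True)
                - xhat * (gx_hat * xhat).mean(axis=-1, keepdims=True)
            )
            return (gx, g_gain, g_bias)

        return Tensor._make(out_data, (self, gain, bias), backward)

    def mean(self, axis):
        axes = axis if isinstance(axis, tuple) else (axis,)
        axes = tuple(a % self.data.ndim for a in axes)
        out_data = self.data.mean(axis=axes)
        count = int(np.prod([self.data.shape[a] for a in axes]))
        orig_shape = self.shape

        def backward(g, out):
            g_exp = np.expand_dims(g, axes)
            return (np.broadcast_to(g_exp, orig_shape) / count,)

        return Tensor._make(out_data, (self,), backward)

    def slice_last(self, start: int, stop: int):
        out_data = self.data[..., start:stop]
        orig_shape = self.shape

        def backward(g, out):
            full = np.zeros(orig_shape)
            full[..., start:stop] = g
            return (full,)

        return Tensor._make(out_data, (self,), backward)

    # -- backward pass -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=np.float64)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        grads = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:  # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g, node)
            for p, pg in zip(node._parents, parent_grads):
                if not p.requires_grad or pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


def concat(tensors: list, axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g, out):
        return tuple(np.split(g, splits, axis=axis))

    out = Tensor(out_data, requires_grad=any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = backward
    return out


class SGDMomentum:
    """Gradient descent with classical momentum over a dict of leaf Tensors."""

    def __init__(self, params: dict, lr: float = 1e-2, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = {k: np.zeros_like(t.data) for k, t in params.items()}

    def zero_grad(self):
        for t in self.params.values():
            t.grad = None

    def step(self, clip: float | None = None):
        """Momentum update; ``clip`` bounds each coordinate of the step."""
        self.apply(self.propose(), clip=clip)

    def propose(self) -> dict:
        """Candidate momentum step (does not mutate parameters)."""
        out = {}
        for k, t in self.params.items():
            if t.grad is None:
                continue
            out[k] = self.momentum * self.velocity[k] - self.lr * t.grad
        return out

    def apply(self, step: dict, clip: float | None = None):
        for k, v in step.items():
            if clip is not None:
                v = np.clip(v, -clip, clip)
            self.velocity[k] = v
            self.params[k].data = self.params[k].data + v

    def undo(self, step: dict):
        """Roll back a just-applied step (velocity is overwritten by the
        caller's next ``apply``)."""
        for k, v in step.items():
            self.params[k].data = self.params[k].data - v

    def state_copy(self) -> dict:
        return {
            "data": {k: t.data.copy() for k, t in self.params.items()},
            "velocity": {k: v.copy() for k, v in self.velocity.items()},
        }

    def restore(self, state: dict):
        for k, t in self.params.items():
            t.data = state["data"][k].copy()
        self.velocity = {k: v.copy() for k, v in state["velocity"].items()}
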