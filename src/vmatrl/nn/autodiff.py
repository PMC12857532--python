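"""Minimal reverse-mode tensor autodiff on numpy.

Supports exactly the operations the tandem policy networks and the PPO /
behavioral-cloning losses need: broadcast arithmetic, matmul, 3D convolution
(im2col), reductions, shape ops, the activation functions of the network
heads, and clipped/min-composed surrogate terms.  Gradients are accumulated
by topological-order backward passes; every op is gradient-checked against
central differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "minimum", "maximum", "conv3d"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward):
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
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

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))
        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))
        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g):
            return (_unbroadcast(g / other.data, self.data.shape),
                    _unbroadcast(-g * self.data / other.data ** 2, other.data.shape))
        return Tensor._from_op(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(g):
            return (g * e * self.data ** (e - 1.0),)
        return Tensor._from_op(self.data ** e, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))
        return Tensor._from_op(self.data @ other.data, (self, other), backward)

    # -- elementwise functions -----------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._from_op(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * (1.0 - out_data ** 2),))

    def relu(self):
        mask = self.data > 0

        def backward(g):
            return (g * mask,)
        return Tensor._from_op(np.where(mask, self.data, 0.0), (self,), backward)

    def softplus(self):
        # numerically stable log(1 + exp(x))
        out_data = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._from_op(out_data, (self,), lambda g: (g * sig,))

    def clip(self, lo: float, hi: float):
        inside = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            return (g * inside,)
        return Tensor._from_op(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.data.shape).copy(),)
        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops -------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._from_op(self.data.reshape(shape), (self,),
                               lambda g: (g.reshape(old),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        return Tensor._from_op(self.data.transpose(axes), (self,),
                               lambda g: (g.transpose(inv),))

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)
        return Tensor._from_op(self.data[idx], (self,), backward)

    # -- autodiff driver -------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:  # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg
        # nodes that are both leaves and intermediate roots
        if self._backward is None and self.requires_grad and self.grad is None:
            self.grad = np.asarray(grad, dtype=np.float64)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))
    return Tensor._from_op(np.concatenate([t.data for t in tensors], axis=axis),
                           tuple(tensors), backward)


def minimum(a: Tensor, b: Tensor) -> Tensor:
    a, b = Tensor._wrap(a), Tensor._wrap(b)
    take_a = a.data <= b.data

    def backward(g):
        return (_unbroadcast(g * take_a, a.data.shape),
                _unbroadcast(g * ~take_a, b.data.shape))
    return Tensor._from_op(np.minimum(a.data, b.data), (a, b), backward)


def maximum(a: Tensor, b: Tensor) -> Tensor:
    a, b = Tensor._wrap(a), Tensor._wrap(b)
    take_a = a.data >= b.data

    def backward(g):
        return (_unbroadcast(g * take_a, a.data.shape),
                _unbroadcast(g * ~take_a, b.data.shape))
    return Tensor._from_op(np.maximum(a.data, b.data), (a, b), backward)


def conv3d(x: Tensor, weight: Tensor, bias: Tensor,
           stride: int = 1, padding: int = 0) -> Tensor:
    """3D convolution, NCDHW layout, cubic kernel, via im2col.

    ``x``: (B, Cin, D, H, W); ``weight``: (Cout, Cin, k, k, k); ``bias``: (Cout,).
    """
    x, weight, bias = Tensor._wrap(x), Tensor._wrap(weight), Tensor._wrap(bias)
    B, Cin, D, H, W = x.data.shape
    Cout, _, k, _, _ = weight.data.shape
    s, p = stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    Do = (D + 2 * p - k) // s + 1
    Ho = (H + 2 * p - k) // s + 1
    Wo = (W + 2 * p - k) // s + 1

    def _views(arr):
        # slice view of arr at kernel offset (i, j, k): (B, C, Do, Ho, Wo)
        return lambda i, j, kk: arr[:, :, i:i + s * Do:s, j:j + s * Ho:s,
                                    kk:kk + s * Wo:s]

    view = _views(xp)
    w = weight.data
    out = np.tile(bias.data.reshape(1, Cout, 1, 1, 1), (B, 1, Do, Ho, Wo)).astype(np.float64)
    for i in range(k):
        for j in range(k):
            for kk in range(k):
                # contract over Cin: (B,Cin,P) x (Cout,Cin) -> (B,Cout,P)
                v = view(i, j, kk).reshape(B, Cin, -1)
                out += (w[:, :, i, j, kk] @ v).reshape(B, Cout, Do, Ho, Wo)

    def backward(g):
        g2 = g.reshape(B, Cout, -1)
        gb = g.sum(axis=(0, 2, 3, 4))
        gw = np.empty_like(w)
        gxp = np.zeros_like(xp)
        gview = _views(gxp)
        for i in range(k):
            for j in range(k):
                for kk in range(k):
                    v = view(i, j, kk).reshape(B, Cin, -1)
                    # (B,Cout,P)x(B,Cin,P) -> (Cout,Cin)
                    gw[:, :, i, j, kk] = np.einsum("bop,bcp->oc", g2, v)
                    gview(i, j, kk)[...] += (
                        w[:, :, i, j, kk].T @ g2).reshape(B, Cin, Do, Ho, Wo)
        gx = gxp[:, :, p:p + D, p:p + H, p:p + W] if p > 0 else gxp
        return (gx, gw, gb)

    return Tensor._from_op(out, (x, weight, bias), backward)
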