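"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the synthesis networks: broadcast-aware
elementwise arithmetic, matmul, im2col convolution, nearest upsampling,
average pooling, reductions and the usual activations.  A :class:`Tensor`
wraps a float32 ndarray and records its parents plus a closure that
propagates the output gradient; :meth:`Tensor.backward` runs the closures
in reverse topological order.

Design choices: float32 end to end; gradients are accumulated for every
node in the graph (graphs here are small and short-lived); convolution
caches its im2col matrix for the backward pass, trading memory for speed,
which is the right trade at the 64x64 desk profile this package trains at.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
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
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # -- infrastructure ------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            # copy: g may alias another node's grad buffer (e.g. identity-
            # shaped unbroadcast) and later in-place adds must not leak
            self.grad = np.array(g, dtype=np.float32)
        else:
            self.grad += g

    def backward(self) -> None:
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bwd
        return out

    def pow(self, exponent: float):
        out = Tensor(self.data**exponent, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = bwd
        return out

    __pow__ = pow

    def exp(self):
        out = Tensor(np.exp(self.data), (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * out.data)
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * np.sign(self.data)
        )
        return out

    # -- activations ---------------------------------------------------

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * (self.data > 0)
        )
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data), (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * np.where(self.data > 0, 1.0, slope).astype(np.float32)
        )
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * out.data * (1.0 - out.data)
        )
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * (1.0 - out.data**2)
        )
        return out

    # -- reductions / shaping -------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g.reshape(self.data.shape)
        )
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bwd
        return out

    # -- spatial ops (NCHW) ---------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """2D convolution (cross-correlation), NCHW x (O, C, kh, kw).

        Computed as a sum of per-tap batched GEMMs, which keeps every
        copy in contiguous row-sized chunks (a plain im2col gather is an
        order of magnitude slower in numpy at these shapes).
        """
        x, w = self.data, weight.data
        n, cin, h, wid = x.shape
        cout, cin2, kh, kw = w.shape
        assert cin == cin2, "channel mismatch"
        s, p = stride, padding
        ho = (h + 2 * p - kh) // s + 1
        wo = (wid + 2 * p - kw) // s + 1
        hw = ho * wo
        ntaps = kh * kw
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        taps = [(i, j) for i in range(kh) for j in range(kw)]
        # gather taps into (n, cin, ntaps, ho, wo): each copy moves
        # contiguous wo-sized rows, and the flattened (cin, tap) axis
        # matches w.reshape(cout, cin*kh*kw)'s index order
        xs = np.empty((n, cin, ntaps, ho, wo), dtype=np.float32)
        for t, (i, j) in enumerate(taps):
            xs[:, :, t] = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
        xsm = xs.reshape(n, cin * ntaps, hw)
        wm = w.reshape(cout, cin * ntaps)
        y = (wm @ xsm).reshape(n, cout, ho, wo)
        if bias is not None:
            y = y + bias.data.reshape(1, cout, 1, 1)
        parents = (self, weight) + ((bias,) if bias is not None else ())
        out = Tensor(y, parents)

        def bwd(g):
            gm = np.ascontiguousarray(g).reshape(n, cout, hw)
            if weight.requires_grad:
                dw = np.matmul(gm, xsm.transpose(0, 2, 1)).sum(axis=0)
                weight._accumulate(dw.reshape(w.shape))
            if bias is not None and bias.requires_grad:
                bias._accumulate(gm.sum(axis=(0, 2)))
            if self.requires_grad:
                dxs = np.matmul(wm.T, gm).reshape(n, cin, ntaps, ho, wo)
                dxp = np.zeros((n, cin, h + 2 * p, wid + 2 * p), dtype=np.float32)
                for t, (i, j) in enumerate(taps):
                    dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dxs[
                        :, :, t
                    ]
                self._accumulate(dxp[:, :, p : p + h, p : p + wid] if p else dxp)

        out._backward = bwd
        return out

    def upsample2x(self):
        """Nearest-neighbour 2x upsampling on the two trailing axes."""
        y = self.data.repeat(2, axis=-2).repeat(2, axis=-1)
        out = Tensor(y, (self,))

        def bwd(g):
            if self.requires_grad:
                n, c, h2, w2 = g.shape
                self._accumulate(
                    g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
                )

        out._backward = bwd
        return out

    def avg_pool2x(self):
        """2x2 average pooling on the two trailing axes."""
        n, c, h, w = self.data.shape
        y = self.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
        out = Tensor(y, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(
                    g.repeat(2, axis=-2).repeat(2, axis=-1) * 0.25
                )

        out._backward = bwd
        return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out
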