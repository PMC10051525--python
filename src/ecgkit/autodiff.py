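"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Provides exactly the operations the 1D convolutional network needs:
elementwise arithmetic, matrix multiplication, strided 1D convolution,
max-pooling, reductions, and the sigmoid/ReLU nonlinearities. Gradients
propagate through a dynamically built tape; broadcasting is supported and
gradients are summed back to the parent shape.

All data is float64. The engine is single-threaded and deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing ------------------------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        """Accumulate gradients of `self` (a scalar unless grad is given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._backward = None
                node._parents = ()

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            # take the array as-is; no op mutates gradients in place
            self.grad = grad
        else:
            self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / other.data**2)

        return self._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, expo: float):
        def bw(g):
            self._accum(g * expo * self.data ** (expo - 1))

        return self._make(self.data**expo, (self,), bw)

    def __matmul__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bw)

    # -- nonlinearities and elementwise functions ----------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accum(g * 0.5 / out_data)

        return self._make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def bw(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), bw)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through where inside the range."""
        mask = (self.data > lo) & (self.data < hi)

        def bw(g):
            self._accum(g * mask)

        return self._make(np.clip(self.data, lo, hi), (self,), bw)

    def maximum(self, other):
        other = self._wrap(other)
        take_self = self.data >= other.data

        def bw(g):
            if self.requires_grad:
                self._accum(g * take_self)
            if other.requires_grad:
                other._accum(g * ~take_self)

        return self._make(np.maximum(self.data, other.data), (self, other), bw)

    # -- reductions / reshapes -----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def bw(g):
            self._accum(g.reshape(orig))

        return self._make(self.data.reshape(shape), (self,), bw)

    # -- structured ops for the 1D CNN ---------------------------------------
    def conv1d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, pad: int = 0):
        """Temporal convolution.

        self: (B, T, C_in); weight: (K, C_in, C_out); bias: (C_out,).
        Output: (B, T_out, C_out) with T_out = (T + 2*pad - K)//stride + 1.
        """
        weight = self._wrap(weight)
        x = self.data
        B, T, Cin = x.shape
        K, Cin_w, Cout = weight.data.shape
        if Cin_w != Cin:
            raise ValueError(f"channel mismatch: input {Cin}, weight {Cin_w}")
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0))) if pad else x
        Tp = xp.shape[1]
        if Tp < K:
            raise ValueError("input shorter than kernel after padding")
        Tout = (Tp - K) // stride + 1
        cols = np.empty((B, Tout, K, Cin))
        for k in range(K):
            cols[:, :, k, :] = xp[:, k : k + Tout * stride : stride, :]
        wmat = weight.data.reshape(K * Cin, Cout)
        out = cols.reshape(B * Tout, K * Cin) @ wmat
        out = out.reshape(B, Tout, Cout)
        parents = [self, weight]
        if bias is not None:
            bias = self._wrap(bias)
            out = out + bias.data
            parents.append(bias)

        def bw(g):
            gf = g.reshape(B * Tout, Cout)
            if weight.requires_grad:
                gw = cols.reshape(B * Tout, K * Cin).T @ gf
                weight._accum(gw.reshape(K, Cin, Cout))
            if bias is not None and bias.requires_grad:
                bias._accum(gf.sum(axis=0))
            if self.requires_grad:
                gcols = (gf @ wmat.T).reshape(B, Tout, K, Cin)
                gxp = np.zeros_like(xp)
                for k in range(K):
                    gxp[:, k : k + Tout * stride : stride, :] += gcols[:, :, k, :]
                self._accum(gxp[:, pad : pad + T, :] if pad else gxp)

        return self._make(out, tuple(parents), bw)

    def maxpool1d(self, size: int):
        """Non-overlapping temporal max pooling; trailing remainder dropped."""
        x = self.data
        B, T, C = x.shape
        Tc = T // size
        if Tc < 1:
            raise ValueError(f"input length {T} shorter than pool size {size}")
        xr = x[:, : Tc * size].reshape(B, Tc, size, C)
        idx = xr.argmax(axis=2)
        out = np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]

        def bw(g):
            gx = np.zeros((B, Tc, size, C))
            np.put_along_axis(gx, idx[:, :, None, :], g[:, :, None, :], axis=2)
            full = np.zeros_like(x)
            full[:, : Tc * size] = gx.reshape(B, Tc * size, C)
            self._accum(full)

        return self._make(out, (self,), bw)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
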