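"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based autodiff core: a :class:`Tensor` wraps an ndarray,
records the operations that produced it, and :meth:`Tensor.backward`
accumulates gradients by reverse topological traversal.  The op set is
exactly what a 1-D convolutional network needs — broadcasting arithmetic,
exp/log/sigmoid/SiLU, axis reductions, matmul, and a grouped same-padded
1-D convolution — nothing more.  Gradients of every op are analytic and are
verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (reverses numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes broadcast from size 1
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def _as_tensor(value) -> "Tensor":
    if isinstance(value, Tensor):
        return value
    return Tensor(np.asarray(value, dtype=float), requires_grad=False)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: Array | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, grad={'yes' if self.requires_grad else 'no'})"

    # -- graph construction helpers -----------------------------------------

    @staticmethod
    def _make(data: Array, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._prev = parents
            out._backward = backward
        return out

    def _accumulate(self, grad: Array) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward(out):
            self._accumulate(_unbroadcast(out.grad, self.shape))
            other._accumulate(_unbroadcast(out.grad, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(out):
            self._accumulate(-out.grad)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def backward(out):
            self._accumulate(_unbroadcast(out.grad * other.data, self.shape))
            other._accumulate(_unbroadcast(out.grad * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_data = self.data / other.data

        def backward(out):
            self._accumulate(_unbroadcast(out.grad / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-out.grad * self.data / other.data**2, other.shape)
            )

        return Tensor._make(out_data, (self, other), backward)

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(out):
            self._accumulate(out.grad * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), backward)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(out):
            self._accumulate(out.grad * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(out):
            self._accumulate(out.grad / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sigmoid(self):
        s = expit(self.data)

        def backward(out):
            self._accumulate(out.grad * s * (1.0 - s))

        return Tensor._make(s, (self,), backward)

    def silu(self):
        """x * sigmoid(x) (the SiLU / swish activation)."""
        s = expit(self.data)
        out_data = self.data * s

        def backward(out):
            self._accumulate(out.grad * (s * (1.0 + self.data * (1.0 - s))))

        return Tensor._make(out_data, (self,), backward)

    # -- reductions and shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(out):
            grad = out.grad
            if axis is not None and not keepdims:
                grad = np.expand_dims(grad, axis)
            self._accumulate(np.broadcast_to(grad, self.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        old_shape = self.shape

        def backward(out):
            self._accumulate(out.grad.reshape(old_shape))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    # -- linear algebra --------------------------------------------------------

    def matmul(self, other: "Tensor"):
        other = _as_tensor(other)
        out_data = self.data @ other.data

        def backward(out):
            self._accumulate(out.grad @ other.data.T)
            other._accumulate(self.data.T @ out.grad)

        return Tensor._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # -- backward pass ---------------------------------------------------------

    def backward(self, grad: Array | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for parent in node._prev:
                if id(parent) not in visited:
                    stack.append((parent, False))
        self.grad = np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None = None, groups: int = 1) -> Tensor:
    """Grouped 1-D convolution with "same" zero padding (odd kernel, stride 1).

    ``x`` is (batch, in_channels, length); ``weight`` is
    (out_channels, in_channels // groups, kernel).
    """
    B, Cin, L = x.shape
    Cout, Cg, K = weight.shape
    if K % 2 != 1:
        raise ValueError("kernel size must be odd for same padding")
    if Cin != Cg * groups or Cout % groups:
        raise ValueError(
            f"channel/group mismatch: in={Cin}, weight expects {Cg}x{groups}, out={Cout}"
        )
    pad = K // 2
    og = Cout // groups
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    out_data = np.zeros((B, Cout, L))
    for g in range(groups):
        xg = xp[:, g * Cg : (g + 1) * Cg]
        wg = weight.data[g * og : (g + 1) * og]
        for k in range(K):
            out_data[:, g * og : (g + 1) * og] += np.einsum(
                "oc,bcl->bol", wg[:, :, k], xg[:, :, k : k + L], optimize=True
            )
    if bias is not None:
        out_data += bias.data[None, :, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(out):
        dout = out.grad
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(weight.data)
        for g in range(groups):
            dog = dout[:, g * og : (g + 1) * og]
            xg = xp[:, g * Cg : (g + 1) * Cg]
            wg = weight.data[g * og : (g + 1) * og]
            for k in range(K):
                dxp[:, g * Cg : (g + 1) * Cg, k : k + L] += np.einsum(
                    "oc,bol->bcl", wg[:, :, k], dog, optimize=True
                )
                dw[g * og : (g + 1) * og, :, k] += np.einsum(
                    "bol,bcl->oc", dog, xg[:, :, k : k + L], optimize=True
                )
        x._accumulate(dxp[:, :, pad : pad + L] if pad else dxp)
        weight._accumulate(dw)
        if bias is not None:
            bias._accumulate(dout.sum(axis=(0, 2)))

    return Tensor._make(out_data, parents, backward)


def log_softmax(logits: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-softmax along ``axis``."""
    shift = logits - logits.data.max(axis=axis, keepdims=True)
    return shift - shift.exp().sum(axis=axis, keepdims=True).log()
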