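"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package trains small 1-D convolutional/recurrent networks on CPU; this
module supplies exactly the tensor operations those networks need (broadcast
arithmetic, matmul, strided 1-D convolution, reductions, activations,
indexing) with gradients.  A :class:`Tensor` records its parents and a
backward closure; :meth:`Tensor.backward` runs reverse topological order.

The engine is deliberately small and deterministic: no in-place mutation of
graph tensors, float64 throughout, no hidden global state.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "stack", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager that disables graph construction."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad and _grad_enabled
        self.grad: np.ndarray | None = None
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        req = _grad_enabled and any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req, parents=tuple(parents), backward=backward)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff core -------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        global _current_grads
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without gradient on non-scalar")
            grad = np.ones_like(self.data)
        topo = _toposort(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        prev, _current_grads = _current_grads, grads
        try:
            for node in topo:
                g = grads.pop(id(node), None)
                if g is None:
                    continue
                node.grad = g.copy() if node.grad is None else node.grad + g
                if node._backward is not None:
                    node._backward(g)
        finally:
            _current_grads = prev

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def bwd(g, a=self, b=other):
            _send(a, _unbroadcast(g, a.data.shape))
            _send(b, _unbroadcast(g, b.data.shape))

        return Tensor._node(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            _send(a, -g)

        return Tensor._node(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def bwd(g, a=self, b=other):
            _send(a, _unbroadcast(g * b.data, a.data.shape))
            _send(b, _unbroadcast(g * a.data, b.data.shape))

        return Tensor._node(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out_data = self.data / other.data

        def bwd(g, a=self, b=other):
            _send(a, _unbroadcast(g / b.data, a.data.shape))
            _send(b, _unbroadcast(-g * a.data / (b.data**2), b.data.shape))

        return Tensor._node(out_data, (self, other), bwd)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def bwd(g, a=self, p=p):
            _send(a, g * p * a.data ** (p - 1))

        return Tensor._node(out_data, (self,), bwd)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data @ other.data

        def bwd(g, a=self, b=other):
            if a.data.ndim == 2 and b.data.ndim == 2:
                _send(a, g @ b.data.T)
                _send(b, a.data.T @ g)
            else:  # pragma: no cover - only 2-D matmul is used
                raise NotImplementedError("matmul gradient only for 2-D operands")

        return Tensor._node(out_data, (self, other), bwd)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g, a=self, o=out_data):
            _send(a, g * o)

        return Tensor._node(out_data, (self,), bwd)

    def log(self):
        def bwd(g, a=self):
            _send(a, g / a.data)

        return Tensor._node(np.log(self.data), (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g, a=self, o=out_data):
            _send(a, g * (1.0 - o**2))

        return Tensor._node(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g, a=self, o=out_data):
            _send(a, g * o * (1.0 - o))

        return Tensor._node(out_data, (self,), bwd)

    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def bwd(g, a=self, m=mask):
            _send(a, g * m)

        return Tensor._node(out_data, (self,), bwd)

    # -- reductions ------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g, a=self, axis=axis, keepdims=keepdims):
            if axis is None:
                _send(a, np.broadcast_to(g, a.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            _send(a, np.broadcast_to(g, a.data.shape).copy())

        return Tensor._node(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        argmax = np.expand_dims(self.data.argmax(axis=axis), axis)

        def bwd(g, a=self, axis=axis, keepdims=keepdims, am=argmax):
            if not keepdims:
                g = np.expand_dims(g, axis)
            gx = np.zeros_like(a.data)
            np.put_along_axis(gx, am, g, axis=axis)
            _send(a, gx)

        return Tensor._node(out_data, (self,), bwd)

    # -- shape manipulation -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bwd(g, a=self, old=old):
            _send(a, g.reshape(old))

        return Tensor._node(self.data.reshape(shape), (self,), bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))

        def bwd(g, a=self, inv=inv):
            _send(a, g.transpose(inv))

        return Tensor._node(self.data.transpose(axes), (self,), bwd)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bwd(g, a=self, idx=idx):
            gx = np.zeros_like(a.data)
            np.add.at(gx, idx, g)
            _send(a, gx)

        return Tensor._node(out_data, (self,), bwd)

    # -- convolution -------------------------------------------------------------
    def conv1d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0) -> "Tensor":
        """1-D cross-correlation: input (B, Cin, L), weight (Cout, Cin, K)."""
        x, w = self.data, weight.data
        B, Cin, L = x.shape
        Cout, Cin_w, K = w.shape
        if Cin != Cin_w:
            raise ValueError(f"conv1d channel mismatch: {Cin} vs {Cin_w}")
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding))) if padding else x
        Lp = xp.shape[-1]
        Lo = (Lp - K) // stride + 1
        if Lo <= 0:
            raise ValueError("conv1d output length would be non-positive")
        # cols: (B, Cin, Lo, K)
        cols = np.lib.stride_tricks.sliding_window_view(xp, K, axis=-1)[:, :, ::stride, :]
        # one large GEMM: (B*Lo, Cin*K) @ (Cin*K, Cout)
        cols2 = cols.transpose(0, 2, 1, 3).reshape(B * Lo, Cin * K)
        wmat = w.reshape(Cout, Cin * K)
        out = (cols2 @ wmat.T).reshape(B, Lo, Cout).transpose(0, 2, 1)
        if bias is not None:
            out = out + bias.data[None, :, None]

        def bwd(g, a=self, wt=weight, bt=bias, cols2=cols2, wmat=wmat,
                B=B, Cin=Cin, L=L, K=K, Lo=Lo, Lp=Lp,
                stride=stride, padding=padding):
            gout = g.transpose(0, 2, 1).reshape(B * Lo, Cout)  # (B*Lo, Cout)
            if wt.requires_grad:
                gw = (gout.T @ cols2).reshape(Cout, Cin, K)
                _send(wt, gw)
            if bt is not None and bt.requires_grad:
                _send(bt, g.sum(axis=(0, 2)))
            if a.requires_grad:
                gcols2 = gout @ wmat  # (B*Lo, Cin*K)
                gcols = gcols2.reshape(B, Lo, Cin, K).transpose(0, 2, 3, 1)
                gxp = np.zeros((B, Cin, Lp))
                for k in range(K):
                    gxp[:, :, k : k + stride * Lo : stride] += gcols[:, :, k, :]
                _send(a, gxp[:, :, padding : padding + L] if padding else gxp)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._node(out, parents, bwd)

    def dropout(self, p: float, rng: np.random.Generator) -> "Tensor":
        """Inverted dropout; identity when p == 0."""
        if p <= 0:
            return self
        mask = (rng.random(self.data.shape) >= p) / (1.0 - p)
        return self * Tensor(mask)


def _send(t: Tensor, g: np.ndarray) -> None:
    """Route a gradient contribution to tensor ``t`` during a backward pass."""
    if not t.requires_grad:
        return
    acc = _current_grads
    if acc is None:  # pragma: no cover - backward always sets it
        raise RuntimeError("gradient routed outside a backward pass")
    if id(t) in acc:
        acc[id(t)] = acc[id(t)] + g
    else:
        acc[id(t)] = g


_current_grads: dict[int, np.ndarray] | None = None


def _toposort(root: Tensor) -> list[Tensor]:
    """Reverse topological order (root first) over grad-requiring nodes."""
    order: list[Tensor] = []
    perm: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in perm:
            continue
        perm.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in perm:
                stack.append((p, False))
    order.reverse()
    return order


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in ts]
    out_data = np.concatenate([t.data for t in ts], axis=axis)

    def bwd(g, ts=ts, sizes=sizes, axis=axis):
        offs = np.cumsum([0] + sizes)
        for t, a, b in zip(ts, offs[:-1], offs[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            _send(t, g[tuple(sl)])

    return Tensor._node(out_data, tuple(ts), bwd)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [Tensor._lift(t) for t in tensors]
    out_data = np.stack([t.data for t in ts], axis=axis)

    def bwd(g, ts=ts, axis=axis):
        for i, t in enumerate(ts):
            _send(t, np.take(g, i, axis=axis))

    return Tensor._node(out_data, tuple(ts), bwd)
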