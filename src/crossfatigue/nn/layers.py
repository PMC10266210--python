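"""Neural-network layers on top of the autodiff engine.

Layers follow the familiar module pattern: parameters are named tensors,
``train()``/``eval()`` toggle dropout and batch-norm statistics, and state
dicts are plain name -> ndarray mappings so checkpoints serialize without a
framework.  Initialization is Kaiming/Glorot-style and driven entirely by an
explicit :class:`numpy.random.Generator`, which is what makes whole training
runs bit-reproducible on CPU.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Tensor, concat

__all__ = [
    "Module",
    "Linear",
    "Conv1d",
    "BatchNorm1d",
    "GRU",
    "Dropout",
    "ReLU",
    "Sequential",
]


class Module:
    """Base class: child modules and parameters are discovered by attribute."""

    def __init__(self) -> None:
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def children(self) -> Iterator["Module"]:
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        yield v

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield from v.named_parameters(f"{full}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for c in self.children():
            c.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- checkpointing -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        # buffers (batch-norm running stats)
        for name, value in self._named_buffers(""):
            out[name] = value.copy()
        return out

    def _named_buffers(self, prefix: str) -> Iterator[tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, np.ndarray) and name.startswith("running_"):
                yield full, value
            elif isinstance(value, Module):
                yield from value._named_buffers(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield from v._named_buffers(f"{full}.{i}.")

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self._named_buffers(""))
        for name, arr in state.items():
            if name in params:
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = np.asarray(arr, dtype=np.float64).copy()
            elif name in buffers:
                buffers[name][...] = arr
            else:
                raise KeyError(f"unexpected key in state dict: {name}")


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(_kaiming(rng, (in_dim, out_dim), in_dim), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None, bias: bool = True):
        super().__init__()
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = in_ch * kernel
        self.weight = Tensor(_kaiming(rng, (out_ch, in_ch, kernel), fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm1d(Module):
    """Batch norm over (batch, length) per channel for (B, C, L) inputs."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(n_ch), requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch), requires_grad=True)
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mean) ** 2).mean(axis=(0, 2), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mean = Tensor(self.running_mean[None, :, None])
            var = Tensor(self.running_var[None, :, None])
        xhat = (x - mean) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(1, -1, 1) + self.beta.reshape(1, -1, 1)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        return x.dropout(self.p, self.rng)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class GRU(Module):
    """Single-direction GRU; input (B, L, D), returns the last hidden state.

    Gate convention: z = sigmoid(x Wz + h Uz + bz), r likewise,
    n = tanh(x Wn + r * (h Un) + bn), h' = (1 - z) * n + z * h.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator,
                 n_layers: int = 1):
        super().__init__()
        self.hidden = hidden
        self.n_layers = n_layers
        self.cells = []
        d = in_dim
        for _ in range(n_layers):
            cell = _GRUCell(d, hidden, rng)
            self.cells.append(cell)
            d = hidden

    def forward(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        seq = [x[:, t, :] for t in range(L)]
        for cell in self.cells:
            h = Tensor(np.zeros((B, self.hidden)))
            out = []
            for xt in seq:
                h = cell(xt, h)
                out.append(h)
            seq = out
        return seq[-1]


class _GRUCell(Module):
    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        s = np.sqrt(1.0 / hidden)
        def w(shape):
            return Tensor(rng.uniform(-s, s, size=shape), requires_grad=True)
        self.Wz, self.Uz, self.bz = w((in_dim, hidden)), w((hidden, hidden)), Tensor(np.zeros(hidden), requires_grad=True)
        self.Wr, self.Ur, self.br = w((in_dim, hidden)), w((hidden, hidden)), Tensor(np.zeros(hidden), requires_grad=True)
        self.Wn, self.Un, self.bn = w((in_dim, hidden)), w((hidden, hidden)), Tensor(np.zeros(hidden), requires_grad=True)

    def forward(self, x: Tensor, h: Tensor) -> Tensor:
        z = (x @ self.Wz + h @ self.Uz + self.bz).sigmoid()
        r = (x @ self.Wr + h @ self.Ur + self.br).sigmoid()
        n = (x @ self.Wn + r * (h @ self.Un) + self.bn).tanh()
        return (1.0 - z) * n + z * h
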