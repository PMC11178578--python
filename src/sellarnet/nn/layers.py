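"""Neural-network layers and the module/parameter system on top of autograd."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "set_init_seed",
    "Module",
    "ModuleList",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "ReLU",
    "SGD",
]

_INIT_RNG = np.random.default_rng(0)


def set_init_seed(seed: int) -> None:
    """Re-seed weight initialization (call before constructing a model)."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


class Module:
    """Base class: tracks parameters, submodules, buffers and train/eval mode."""

    def __init__(self) -> None:
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, b in self._buffers.items():
            yield prefix + name, b
        for mname, m in self._modules.items():
            yield from m.named_buffers(prefix + mname + ".")

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def set_requires_grad(self, flag: bool) -> None:
        for p in self.parameters():
            p.requires_grad = flag

    def count_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param.{n}": p.data for n, p in self.named_parameters()}
        state.update({f"buffer.{n}": b for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for n, p in self.named_parameters():
            p.data = np.asarray(state[f"param.{n}"], dtype=np.float32)
        for n, b in self.named_buffers():
            b[...] = state[f"buffer.{n}"]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, m: Module) -> None:
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = ModuleList(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.layers:
            x = m(x)
        return x


class Conv2d(Module):
    """3x3/1x1 convolution with He-normal init; padding defaults to 'same'."""

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int,
                 stride: int = 1, padding: int | None = None, bias: bool = False):
        super().__init__()
        k = kernel_size
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        fan_in = in_ch * k * k
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Tensor(
            _INIT_RNG.normal(0.0, std, size=(out_ch, in_ch, k, k)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = ag.conv2d(x, self.weight, stride=self.stride, padding=self.padding)
        if self.bias is not None:
            out = out + self.bias.reshape((1, -1, 1, 1))
        return out


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return ag.batch_norm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum, eps=self.eps,
        )


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        std = float(np.sqrt(2.0 / in_features))
        self.weight = Tensor(
            _INIT_RNG.normal(0.0, std, size=(in_features, out_features)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(x)


class SGD:
    """SGD with classical momentum; skips parameters with requires_grad=False.

    `max_grad_norm` rescales the global gradient norm when it exceeds the
    bound, which keeps the landmark-regression gradients (large by
    construction on the Wing percent scale) from destabilizing the run.
    """

    def __init__(self, params, lr: float = 0.01, momentum: float = 0.9,
                 weight_decay: float = 0.0, max_grad_norm: float | None = 5.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.max_grad_norm = max_grad_norm
        self._velocity: dict[int, np.ndarray] = {}

    def _clip(self) -> None:
        if self.max_grad_norm is None:
            return
        sq = 0.0
        grads = [p.grad for p in self.params if p.requires_grad and p.grad is not None]
        for g in grads:
            sq += float(np.sum(np.square(g, dtype=np.float64)))
        norm = np.sqrt(sq)
        if norm > self.max_grad_norm:
            scale = np.float32(self.max_grad_norm / (norm + 1e-12))
            for g in grads:
                g *= scale

    def step(self) -> None:
        self._clip()
        for p in self.params:
            if not p.requires_grad or p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v = self._velocity.get(id(p))
            v = g if v is None else self.momentum * v + g
            self._velocity[id(p)] = v
            p.data = p.data - self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
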