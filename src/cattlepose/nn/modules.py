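"""Layer modules over the autograd core: parameter registration, train/eval
state, checkpoint (de)serialization and a MAC-counting profiler hook used by
the FLOP counter."""

from __future__ import annotations

import math
from typing import Iterator, Optional

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class _Profiler:
    """Accumulates multiply-accumulate counts during a forward pass."""

    active: Optional["_Profiler"] = None

    def __init__(self):
        self.macs = 0

    def __enter__(self):
        _Profiler.active = self
        return self

    def __exit__(self, *exc):
        _Profiler.active = None

    @classmethod
    def add(cls, macs: int):
        if cls.active is not None:
            cls.active.macs += int(macs)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal -----------------------------------------------------------
    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for n, p in self._params.items():
            yield prefix + n, p
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for n, b in self._buffers.items():
            yield prefix + n, getattr(self, n)
        for n, m in self._modules.items():
            yield from m.named_buffers(prefix + n + ".")

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- checkpointing -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {n: p.data for n, p in self.named_parameters()}
        for n, b in self.named_buffers():
            state["buffer:" + n] = b
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buffer:"):
                buf = buffers[key[len("buffer:"):]]
                np.copyto(buf, value)
            else:
                p = params[key]
                if p.data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                p.data = value.astype(np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, i):
        return self.layers[i]

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._list))] = m
        self._list.append(m)
        return self

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def forward(self, *a, **k):  # pragma: no cover
        raise RuntimeError("ModuleList is a container")


class Identity(Module):
    def forward(self, x):
        return x


def _kaiming(shape, fan_in, rng: np.random.Generator):
    bound = math.sqrt(1.0 / fan_in) if fan_in > 0 else 0.0
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


_default_rng = np.random.default_rng(0)


def seed_init(seed: int) -> None:
    """Reseed the weight-initialization stream (one seeded generator per run)."""
    global _default_rng
    _default_rng = np.random.default_rng(seed)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 bias: bool = True):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels not divisible by groups")
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding
        self.groups = groups
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        self.weight = Parameter(_kaiming(
            (out_channels, in_channels // groups, kernel_size, kernel_size),
            fan_in, _default_rng))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = ag.conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, groups=self.groups)
        _Profiler.add(y.shape[0] * y.shape[2] * y.shape[3] * self.out_channels
                      * (self.in_channels // self.groups)
                      * self.kernel_size * self.kernel_size)
        return y


class ConvTranspose2d(Module):
    """Transposed conv with kernel_size == stride (exact x2 upsampler)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 2,
                 stride: int = 2, bias: bool = True):
        super().__init__()
        if kernel_size != stride:
            raise ValueError("only kernel_size == stride supported")
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size = self.stride = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(_kaiming(
            (in_channels, out_channels, kernel_size, kernel_size), fan_in,
            _default_rng))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = ag.conv_transpose2d(x, self.weight, self.bias, stride=self.stride)
        _Profiler.add(x.shape[0] * x.shape[2] * x.shape[3] * self.in_channels
                      * self.out_channels * self.kernel_size * self.kernel_size)
        return y


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.num_features, self.eps, self.momentum = num_features, eps, momentum
        self.weight = Parameter(np.ones(num_features, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return ag.batchnorm2d(x, self.weight, self.bias, self.running_mean,
                              self.running_var, training=self.training,
                              momentum=self.momentum, eps=self.eps)


class SiLU(Module):
    def forward(self, x):
        return ag.silu(x)


class ReLU(Module):
    def forward(self, x):
        return ag.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return ag.sigmoid(x)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int = 1, padding: int = 0):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x):
        return ag.maxpool2d(x, self.kernel_size, self.stride, self.padding)


class UpsampleNearest2(Module):
    def forward(self, x):
        return ag.upsample_nearest2(x)


def save_checkpoint(path, module: Module, meta: Optional[dict] = None) -> None:
    state = module.state_dict()
    if meta:
        state = dict(state)
        state["__meta__"] = np.frombuffer(
            __import__("json").dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], dict]:
    with np.load(path) as npz:
        state = {k: npz[k] for k in npz.files}
    meta = {}
    if "__meta__" in state:
        meta = __import__("json").loads(state.pop("__meta__").tobytes().decode())
    return state, meta
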