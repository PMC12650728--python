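"""Layer/module abstractions over the autodiff core.

Mirrors the familiar deep-learning layer API at the minimal scale this
package needs: parameter registration, state dicts, and a handful of
layers (convolutions, group normalization, sequential containers).
Convolutions feeding a normalization layer are bias-free.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Tensor
from . import functional as F


class Parameter(Tensor):
    """A tensor registered as a learnable parameter of a module."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # ---------------------------------------------------------------- traversal
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield (f"{prefix}{name}", p)
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # --------------------------------------------------------------- state dict
    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch; missing={sorted(missing)}, unexpected={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {name!r}: checkpoint shape {arr.shape} != model shape {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int | str = "same",
        pad_mode: str = "zeros",
        bias: bool = False,
        zero_init: bool = False,
    ):
        super().__init__()
        k = kernel_size
        fan_in = in_channels * k * k
        if zero_init:
            w = np.zeros((out_channels, in_channels, k, k), dtype=np.float32)
        else:
            w = he_normal(rng, (out_channels, in_channels, k, k), fan_in)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None
        self.stride = stride
        self.padding = padding if padding != "same" or stride == 1 else k // 2
        self.pad_mode = pad_mode

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, bias=self.bias, stride=self.stride, padding=self.padding, pad_mode=self.pad_mode)


class ConvTranspose2d(Module):
    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator, kernel_size: int = 2, stride: int = 2):
        super().__init__()
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(he_normal(rng, (in_channels, out_channels, kernel_size, kernel_size), fan_in))
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.weight, stride=self.stride)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel_size: int, rng: np.random.Generator, pad_mode: str = "edge"):
        super().__init__()
        self.weight = Parameter(he_normal(rng, (channels, kernel_size, kernel_size), kernel_size * kernel_size))
        self.pad_mode = pad_mode

    def forward(self, x: Tensor) -> Tensor:
        return F.depthwise_conv2d(x, self.weight, pad_mode=self.pad_mode)


def auto_groups(channels: int, target: int = 8) -> int:
    """Largest divisor of ``channels`` not exceeding ``target``."""
    for g in range(min(target, channels), 0, -1):
        if channels % g == 0:
            return g
    return 1


class GroupNorm(Module):
    """Group normalization over channel groups, batch-size independent.

    ``eps`` floors the variance so constant inputs stay finite.
    """

    def __init__(self, channels: int, groups: int | None = None, eps: float = 1e-5):
        super().__init__()
        if groups is None:
            groups = auto_groups(channels)
        if channels % groups != 0:
            raise ValueError(f"GroupNorm: {channels} channels not divisible by {groups} groups")
        self.groups = groups
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return F.group_norm(x, self.gamma, self.beta, self.groups, self.eps)


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.silu(x)
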