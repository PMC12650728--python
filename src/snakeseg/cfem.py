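"""Composite Feature Extraction Module (CFEM).

Two stages, both size- and channel-preserving:

1. **Tubular feature extraction** — group-normalize the input, run
   directional dynamic snake convolutions along the x and y axes,
   concatenate the two directional maps (x first, then y), and integrate
   them with a 3x3 convolution + group normalization + SiLU.
2. **Dual-path expansion/contraction** — two parallel 1x1 expansions to
   ``expansion_ratio * C`` channels, elementwise gating
   ``Finter = Fexp1 * GELU(Fexp2)`` (a gated-linear-unit interaction),
   1x1 contraction back to C channels, depthwise 7x7 integration, and a
   residual connection back to the module input.

The channel expansion is a 1x1 projection: "expansion rate" refers to the
channel width of the intermediate representation, which the contraction
restores, keeping the output consistent with the input size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .exceptions import ConfigurationError, ShapeError
from .nn import Tensor, as_tensor, concatenate
from .nn import functional as F
from .nn.modules import auto_groups
from .snake_conv import DynamicSnakeConv, SnakeKernelSpec

__all__ = ["CfemConfig", "CFEM"]


@dataclass(frozen=True)
class CfemConfig:
    channels: int
    expansion_ratio: int = 4
    depthwise_kernel: int = 7
    gn_groups: int | None = None
    kernel_length: int = 9
    max_step: float = 1.0

    def __post_init__(self):
        groups = self.resolved_groups
        if self.channels % groups != 0:
            raise ConfigurationError(f"channels {self.channels} not divisible by gn_groups {groups}")
        if self.expansion_ratio < 1:
            raise ConfigurationError("expansion_ratio must be >= 1")

    @property
    def resolved_groups(self) -> int:
        return self.gn_groups if self.gn_groups is not None else auto_groups(self.channels)


class CFEM(nn.Module):
    """Composite feature extraction block; preserves size and channels."""

    def __init__(self, cfg: CfemConfig, rng: np.random.Generator):
        super().__init__()
        C = cfg.channels
        g = cfg.resolved_groups
        self.cfg = cfg
        # tubular stage (two independent normalizations)
        self.gn_in = nn.GroupNorm(C, g)
        self.snake_x = DynamicSnakeConv(
            SnakeKernelSpec("x", C, C, cfg.kernel_length, cfg.max_step), rng
        )
        self.snake_y = DynamicSnakeConv(
            SnakeKernelSpec("y", C, C, cfg.kernel_length, cfg.max_step), rng
        )
        self.integrate = nn.Conv2d(2 * C, C, 3, rng, padding="same")
        self.gn_out = nn.GroupNorm(C, g)
        # dual-path stage
        E = cfg.expansion_ratio * C
        self.expand1 = nn.Conv2d(C, E, 1, rng)
        self.expand2 = nn.Conv2d(C, E, 1, rng)
        self.contract = nn.Conv2d(E, C, 1, rng)
        self.depthwise = nn.DepthwiseConv2d(C, cfg.depthwise_kernel, rng, pad_mode="edge")

    # ------------------------------------------------------------------ stages
    def tubular_features(self, fin) -> Tensor:
        """Directional snake-convolution stage -> C-channel tubular map."""
        fin = as_tensor(fin)
        if fin.shape[1] != self.cfg.channels:
            raise ConfigurationError(
                f"input has {fin.shape[1]} channels, CFEM configured for {self.cfg.channels}"
            )
        fn = self.gn_in(fin)
        fx = self.snake_x(fn)
        fy = self.snake_y(fn)
        fconcat = concatenate([fx, fy], axis=1)
        return F.silu(self.gn_out(self.integrate(fconcat)))

    def dual_path_scale(self, ftube, fin) -> Tensor:
        """Gated expansion/contraction with depthwise integration + residual."""
        ftube, fin = as_tensor(ftube), as_tensor(fin)
        if ftube.shape[2:] != fin.shape[2:]:
            raise ShapeError(f"spatial mismatch: {ftube.shape[2:]} vs {fin.shape[2:]}")
        if fin.shape[1] != self.cfg.channels:
            raise ConfigurationError(
                f"input has {fin.shape[1]} channels, CFEM configured for {self.cfg.channels}"
            )
        finter = self.expand1(ftube) * F.gelu(self.expand2(ftube))
        fcon = self.contract(finter)
        fdepth = self.depthwise(fcon)
        return fdepth + fin

    def forward(self, fin) -> Tensor:
        fin = as_tensor(fin)
        return self.dual_path_scale(self.tubular_features(fin), fin)
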