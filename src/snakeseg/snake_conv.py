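"""Dynamic snake convolution: axis-aligned kernels with deformable taps.

A snake convolution slides a 1-D kernel (default 9 taps) along one image
axis while letting each tap drift perpendicular to that axis along a
learned, continuity-constrained path.  Tap displacements are predicted by
a small convolutional offset head, squashed through tanh (bounding each
step by ``max_step``) and cumulatively summed outward from the center tap,
so adjacent taps can never separate by more than ``max_step`` pixels and
the sampled path stays connected.  The offset head is zero-initialized:
the layer starts out exactly equal to a standard axis-aligned convolution
and learns to bend toward tubular structures during training.

Coordinate convention: pixel centers at integer coordinates, origin at the
top-left, (row, column) order.  Samples outside the image clamp to the
border (no zero-padding halo around thin vessels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .exceptions import ConfigurationError
from .nn import Tensor, as_tensor
from .nn import functional as F

__all__ = [
    "SnakeKernelSpec",
    "OffsetField",
    "DynamicSnakeConv",
    "predict_offsets",
    "sample_bilinear",
    "snake_convolve",
]


@dataclass(frozen=True)
class SnakeKernelSpec:
    """Geometry of one directional snake kernel.

    ``axis='x'`` spreads the taps horizontally (the paper's x-axis kernel);
    ``axis='y'`` spreads them vertically.  Offsets displace taps along the
    perpendicular axis.
    """

    axis: str
    in_channels: int
    out_channels: int
    kernel_length: int = 9
    max_step: float = 1.0

    def __post_init__(self):
        if self.axis not in ("x", "y"):
            raise ConfigurationError(f"axis must be 'x' or 'y', got {self.axis!r}")
        if self.kernel_length % 2 != 1 or self.kernel_length < 1:
            raise ConfigurationError("kernel_length must be a positive odd integer")
        if self.max_step <= 0:
            raise ConfigurationError("max_step must be positive")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ConfigurationError("channel counts must be positive")


@dataclass
class OffsetField:
    """Per-position, per-tap perpendicular displacements in pixels.

    ``offsets`` has shape (batch, kernel_length, height, width); the center
    tap is the anchor and its offset is exactly zero.
    """

    offsets: Tensor
    spec: SnakeKernelSpec

    @property
    def shape(self):
        return self.offsets.shape


def _cumulative_matrix(kernel_length: int) -> np.ndarray:
    """L such that offsets = L @ increments accumulates outward from center.

    For taps k beyond the center c, offset_k = sum of increments c+1..k; for
    taps before it, offset_k = sum of increments k..c-1.  Row c is zero, so
    the center tap is the fixed anchor of the path.
    """
    c = kernel_length // 2
    L = np.zeros((kernel_length, kernel_length), dtype=np.float32)
    for k in range(kernel_length):
        if k > c:
            L[k, c + 1 : k + 1] = 1.0
        elif k < c:
            L[k, k:c] = 1.0
    return L


class DynamicSnakeConv(nn.Module):
    """One directional snake-convolution layer (offset head + tap weights)."""

    def __init__(self, spec: SnakeKernelSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        # zero-initialized offset head: the layer starts as a plain convolution
        self.offset_head = nn.Conv2d(
            spec.in_channels, spec.kernel_length, 3, rng, padding="same",
            pad_mode="edge", bias=True, zero_init=True,
        )
        fan_in = spec.in_channels * spec.kernel_length
        self.weight = nn.Parameter(
            nn.modules.he_normal(rng, (spec.out_channels, spec.in_channels, spec.kernel_length), fan_in)
        )

    def predict_offsets(self, x: Tensor) -> OffsetField:
        return predict_offsets(x, self.spec, self.offset_head)

    def forward(self, x: Tensor) -> Tensor:
        return snake_convolve(x, self.spec, self.predict_offsets(x), self.weight)


def predict_offsets(x, spec: SnakeKernelSpec, offset_head: nn.Module) -> OffsetField:
    """Predict the continuity-constrained tap displacement field for ``x``.

    Raw head outputs are squashed by tanh and scaled to ``max_step`` pixels
    per tap-to-tap increment, then cumulatively summed outward from the
    center tap, so |offset_k - offset_{k±1}| <= max_step everywhere.
    """
    x = as_tensor(x)
    if x.ndim != 4:
        raise ConfigurationError("expected a (N, C, H, W) feature map")
    N, C, H, W = x.shape
    if C != spec.in_channels:
        raise ConfigurationError(f"input has {C} channels, spec expects {spec.in_channels}")
    raw = offset_head(x)  # (N, K, H, W)
    increments = raw.tanh() * np.float32(spec.max_step)
    L = as_tensor(_cumulative_matrix(spec.kernel_length))
    flat = increments.reshape(N, spec.kernel_length, H * W)
    offsets = (L @ flat).reshape(N, spec.kernel_length, H, W)
    return OffsetField(offsets=offsets, spec=spec)


def sample_bilinear(x, rows, cols) -> Tensor:
    """Bilinearly interpolate ``x`` (N,C,H,W) at fractional (row, col) points.

    Integer coordinates return the stored pixel values exactly; out-of-range
    coordinates are clamped to the border; non-finite coordinates raise.
    """
    return F.bilinear_sample(x, rows, cols)


def snake_convolve(x, spec: SnakeKernelSpec, offsets: OffsetField, weights, bias=None) -> Tensor:
    """Convolve along the deformed tap path.

    ``weights`` has shape (out_channels, in_channels, kernel_length).  Each
    output value is the weighted sum of ``kernel_length`` bilinear samples
    taken along the offset path; output spatial size equals the input's.
    With a zero offset field this is exactly the standard axis-aligned
    convolution with border-replicated padding.
    """
    x = as_tensor(x)
    weights = as_tensor(weights)
    N, C, H, W = x.shape
    K = spec.kernel_length
    if C != spec.in_channels:
        raise ConfigurationError(f"input has {C} channels, spec expects {spec.in_channels}")
    if offsets.spec is not spec and offsets.spec != spec:
        raise ConfigurationError("offset field was produced for a different kernel spec")
    if tuple(offsets.offsets.shape) != (N, K, H, W):
        raise ConfigurationError(
            f"offset field shape {tuple(offsets.offsets.shape)} does not match (N,K,H,W)=({N},{K},{H},{W})"
        )
    if tuple(weights.shape) != (spec.out_channels, spec.in_channels, K):
        raise ConfigurationError(f"weights shape {tuple(weights.shape)} != (out, in, K)")

    out = F.snake_sample_contract(x, offsets.offsets, weights, spec.axis)
    if bias is not None:
        out = out + as_tensor(bias).reshape(1, spec.out_channels, 1, 1)
    return out
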