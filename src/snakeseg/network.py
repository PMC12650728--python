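"""U-shaped encoder-decoder segmentation network.

Layout (widths shown for base width C0):

* stem 3x3 convolution: image channels -> C0
* 4 encoder stages i = 0..3 at widths C0 * 2^i, each a CFEM followed by a
  stride-2 3x3 downsampling convolution that doubles the channel count
  (the deepest downsample keeps 8*C0, so the bottleneck stays at 8*C0)
* bottleneck CFEM at 8*C0
* 4 decoder stages: 2x2/stride-2 transposed-convolution upsampling to the
  matching encoder width, MCAM-refined skip concatenated and reduced by a
  1x1 convolution, then the stage CFEM
* 1x1 head mapping C0 -> 2 channels (background, foreground) followed by
  an elementwise sigmoid (a softmax head is available behind config).

Every stage obeys the size/channel bookkeeping: downsampling halves the
spatial size and doubles channels, upsampling does the inverse, and CFEM /
MCAM preserve both.  Inputs whose sides are not divisible by 16 are
border-replicate padded up and the output cropped back (or rejected, per
``pad_policy``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .cfem import CFEM, CfemConfig
from .exceptions import ConfigurationError, ShapeError
from .mcam import MCAM, McamConfig
from .nn import Tensor, as_tensor, concatenate, no_grad

__all__ = ["NetworkConfig", "SegmentationOutput", "SnakeSegNet", "build_network", "predict_mask"]

N_STAGES = 4


@dataclass(frozen=True)
class NetworkConfig:
    in_channels: int = 1
    base_width: int = 32
    out_channels: int = 2
    expansion_ratio: int = 4
    depthwise_kernel: int = 7
    kernel_length: int = 9
    max_step: float = 1.0
    compression_ratio: int = 4
    epsilon: float = 1e-4
    t_strategy: str = "global_mean"
    head: str = "sigmoid"
    pad_policy: str = "pad"  # 'pad' (replicate + crop back) or 'strict'

    def __post_init__(self):
        if self.base_width < self.compression_ratio:
            raise ConfigurationError("base_width must be >= compression_ratio")
        if self.head not in ("sigmoid", "softmax"):
            raise ConfigurationError("head must be 'sigmoid' or 'softmax'")
        if self.pad_policy not in ("pad", "strict"):
            raise ConfigurationError("pad_policy must be 'pad' or 'strict'")

    @property
    def stage_widths(self) -> tuple[int, ...]:
        return tuple(self.base_width * 2**i for i in range(N_STAGES))


@dataclass
class SegmentationOutput:
    """Per-pixel class probabilities (2, H, W per item) in (0, 1)."""

    probabilities: np.ndarray  # (N, 2, H, W)

    def mask(self, threshold: float = 0.5) -> np.ndarray:
        return predict_mask(self, threshold)


class SnakeSegNet(nn.Module):
    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        widths = cfg.stage_widths

        def cfem(c):
            return CFEM(
                CfemConfig(
                    channels=c,
                    expansion_ratio=cfg.expansion_ratio,
                    depthwise_kernel=cfg.depthwise_kernel,
                    kernel_length=cfg.kernel_length,
                    max_step=cfg.max_step,
                ),
                rng,
            )

        self.stem = nn.Conv2d(cfg.in_channels, widths[0], 3, rng, padding="same")
        for i, c in enumerate(widths):
            setattr(self, f"enc_cfem{i}", cfem(c))
            c_next = widths[i + 1] if i + 1 < N_STAGES else widths[-1]
            setattr(self, f"down{i}", nn.Conv2d(c, c_next, 3, rng, stride=2, padding=1))
        self.bottleneck = cfem(widths[-1])
        for i, c in enumerate(widths):
            c_below = widths[i + 1] if i + 1 < N_STAGES else widths[-1]
            setattr(self, f"up{i}", nn.ConvTranspose2d(c_below, c, rng))
            setattr(
                self,
                f"mcam{i}",
                MCAM(
                    McamConfig(
                        channels=c,
                        compression_ratio=cfg.compression_ratio,
                        epsilon=cfg.epsilon,
                        t_strategy=cfg.t_strategy,
                    ),
                    rng,
                ),
            )
            setattr(self, f"fuse{i}", nn.Conv2d(2 * c, c, 1, rng))
            setattr(self, f"dec_cfem{i}", cfem(c))
        self.head = nn.Conv2d(widths[0], cfg.out_channels, 1, rng, bias=True)

    # ------------------------------------------------------------------
    def forward_tensor(self, x) -> Tensor:
        """Full differentiable forward pass -> probability Tensor."""
        x = as_tensor(x)
        if x.ndim != 4:
            raise ShapeError("expected input of shape (N, C, H, W)")
        if x.shape[1] != self.cfg.in_channels:
            raise ConfigurationError(
                f"input has {x.shape[1]} channels, network expects {self.cfg.in_channels}"
            )
        N, _, H, W = x.shape
        ph = (-H) % 16
        pw = (-W) % 16
        if ph or pw:
            if self.cfg.pad_policy == "strict":
                raise ShapeError(f"input size {H}x{W} not divisible by 16 (pad_policy='strict')")
            x = Tensor(np.pad(x.data, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="edge"))
        f = self.stem(x)
        skips = []
        for i in range(N_STAGES):
            f = getattr(self, f"enc_cfem{i}")(f)
            skips.append(f)
            f = getattr(self, f"down{i}")(f)
        f = self.bottleneck(f)
        for i in reversed(range(N_STAGES)):
            f = getattr(self, f"up{i}")(f)
            s = getattr(self, f"mcam{i}")(skips[i])
            f = getattr(self, f"fuse{i}")(concatenate([f, s], axis=1))
            f = getattr(self, f"dec_cfem{i}")(f)
        logits = self.head(f)
        if self.cfg.head == "sigmoid":
            probs = logits.sigmoid()
        else:
            shifted = logits - as_tensor(logits.data.max(axis=1, keepdims=True))
            e = shifted.exp()
            probs = e / e.sum(axis=1, keepdims=True)
        # float32 sigmoid saturates to exactly 0/1 for large logits; floor it
        # so probabilities stay strictly inside (0, 1)
        probs = probs.clip(1e-7, 1.0 - 1e-7)
        if ph or pw:
            probs = probs[:, :, :H, :W]
        return probs

    def forward(self, x) -> SegmentationOutput:
        """Inference entry point; no autodiff graph is recorded."""
        with no_grad():
            return SegmentationOutput(probabilities=self.forward_tensor(x).data)


def build_network(cfg: NetworkConfig, seed: int = 0) -> SnakeSegNet:
    """Build a seeded network; parameter count is available via
    ``model.num_parameters()``."""
    rng = np.random.default_rng(seed)
    return SnakeSegNet(cfg, rng)


def predict_mask(output: SegmentationOutput, threshold: float = 0.5) -> np.ndarray:
    """Binarize the foreground channel: probability >= threshold -> 1."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    probs = output.probabilities if isinstance(output, SegmentationOutput) else np.asarray(output)
    fg = probs[:, 1] if probs.ndim == 4 else probs
    return (fg >= threshold).astype(np.uint8)
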