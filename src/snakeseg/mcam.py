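"""Multi-scale Composite Attention Module (MCAM) for skip connections.

Pipeline on an incoming C-channel skip feature map ``Fin``:

1. **Multi-scale fusion** — 1x1 compression to C/4 channels, three
   parallel branches with 1x1 / 3x3 / 5x5 kernels, channel concatenation,
   group normalization and a 1x1 fusion back to C/4 channels (``Fms``).
2. **Spatial attention** — per-position channel mean and max of ``Fms``
   are concatenated (2 channels) and passed through a 7x7 convolution,
   SiLU and a sigmoid, giving a single-channel map ``Ms`` in (0,1);
   ``Fs = Fms * Ms``.
3. **Channel attention** (parameter-free, SimAM-style) — per-channel
   spatial mean and variance of ``Fin`` feed an energy function
   ``Ec = (mu_c - t)^2 / (sigma_c^2 + eps)``; low energy marks important
   channels, and ``Mc = sigmoid(-Ec)`` in (0, 0.5] weights them.

The module output restores ``Fs`` to C channels with a 1x1 expansion,
scales it by ``Mc``, and adds the residual ``Fin``, so the block preserves
size and channel count.

The energy target ``t`` is configurable: ``global_mean`` (default) uses
the mean of ``Fin`` over all channels and positions of each sample, so a
feature map whose channels are all identical receives the neutral weight
``Mc = sigmoid(0) = 0.5``; ``zero`` uses ``t = 0``.  A literal per-pixel
target would collapse the energy to ``sigma^2/(sigma^2+eps)`` and is
deliberately not offered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .exceptions import ConfigurationError
from .nn import Tensor, as_tensor, concatenate
from .nn import functional as F
from .nn.modules import auto_groups

__all__ = ["McamConfig", "MCAM"]


@dataclass(frozen=True)
class McamConfig:
    channels: int
    compression_ratio: int = 4
    branch_kernels: tuple[int, ...] = (1, 3, 5)
    spatial_kernel: int = 7
    epsilon: float = 1e-4
    t_strategy: str = "global_mean"

    def __post_init__(self):
        if self.channels % self.compression_ratio != 0:
            raise ConfigurationError(
                f"channels {self.channels} not divisible by compression_ratio {self.compression_ratio}"
            )
        if self.t_strategy not in ("global_mean", "zero"):
            raise ConfigurationError("t_strategy must be 'global_mean' or 'zero'")
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be positive")


class MCAM(nn.Module):
    def __init__(self, cfg: McamConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        C = cfg.channels
        Cr = C // cfg.compression_ratio
        self.compress = nn.Conv2d(C, Cr, 1, rng)
        for i, k in enumerate(cfg.branch_kernels):
            setattr(self, f"branch{i}", nn.Conv2d(Cr, Cr, k, rng, padding="same", pad_mode="edge"))
        n_branch = len(cfg.branch_kernels)
        self.gn = nn.GroupNorm(n_branch * Cr, auto_groups(n_branch * Cr))
        self.fuse = nn.Conv2d(n_branch * Cr, Cr, 1, rng)
        self.spatial_conv = nn.Conv2d(2, 1, cfg.spatial_kernel, rng, padding="same", pad_mode="edge", bias=True)
        self.expand = nn.Conv2d(Cr, C, 1, rng)

    # ------------------------------------------------------------------ stages
    def multiscale_fuse(self, fin) -> Tensor:
        """Compression + parallel 1/3/5 branches + fused C/4-channel map."""
        fin = as_tensor(fin)
        if fin.shape[1] != self.cfg.channels:
            raise ConfigurationError(
                f"input has {fin.shape[1]} channels, MCAM configured for {self.cfg.channels}"
            )
        z = self.compress(fin)
        branches = [getattr(self, f"branch{i}")(z) for i in range(len(self.cfg.branch_kernels))]
        cat = concatenate(branches, axis=1)
        return self.fuse(self.gn(cat))

    def spatial_attention(self, fms) -> tuple[Tensor, Tensor]:
        """(Ms, Fs): sigmoid spatial map in (0,1) and the weighted features."""
        fms = as_tensor(fms)
        favg = fms.mean(axis=1, keepdims=True)
        fmax = fms.max(axis=1, keepdims=True)
        fcat = concatenate([favg, fmax], axis=1)
        ms = F.silu(self.spatial_conv(fcat)).sigmoid()
        return ms, fms * ms

    def channel_attention_simam(self, fin) -> tuple[Tensor, Tensor]:
        """(Mc, Fc): per-channel energy weights in (0, 0.5] and weighted input.

        Depends only on per-channel spatial statistics, hence invariant to
        any spatial permutation of pixels within a channel.  Single-pixel
        maps have zero variance; the ``epsilon`` floor keeps the energy
        finite and the weights defined.
        """
        fin = as_tensor(fin)
        mu = fin.mean(axis=(2, 3), keepdims=True)  # (N, C, 1, 1)
        var = ((fin - mu) * (fin - mu)).mean(axis=(2, 3), keepdims=True)
        if self.cfg.t_strategy == "global_mean":
            t = fin.mean(axis=(1, 2, 3), keepdims=True)
        else:
            t = as_tensor(np.zeros((1, 1, 1, 1), dtype=np.float32))
        diff = mu - t
        energy = (diff * diff) / (var + self.cfg.epsilon)
        mc = (-energy).sigmoid()
        return mc, fin * mc

    def forward(self, fin) -> Tensor:
        fin = as_tensor(fin)
        fms = self.multiscale_fuse(fin)
        _, fs = self.spatial_attention(fms)
        mc, _ = self.channel_attention_simam(fin)
        return fin + self.expand(fs) * mc
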