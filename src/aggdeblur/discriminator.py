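"""Double-scale adversarial critics: a global critic on a half-resolution
view of the full image and a local patch critic at native resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor
from .nn import Conv2d, Module

__all__ = ["DiscriminatorConfig", "PatchCritic", "build_double_scale_discriminator"]


@dataclass
class DiscriminatorConfig:
    base_width: int = 64
    in_channels: int = 3
    seed: int = 0


class PatchCritic(Module):
    """Three-layer strided patch critic emitting a spatial score map."""

    min_input = 16  # two stride-2 layers + one 4x4 valid-ish conv

    def __init__(self, cfg: DiscriminatorConfig, downsample: bool = False, seed_offset: int = 0):
        rng = np.random.default_rng(cfg.seed + seed_offset)
        w = cfg.base_width
        self.downsample = downsample
        self.conv1 = Conv2d(cfg.in_channels, w, 4, stride=2, padding=1, rng=rng)
        self.conv2 = Conv2d(w, 2 * w, 4, stride=2, padding=1, rng=rng)
        self.conv3 = Conv2d(2 * w, 1, 4, stride=1, padding=1, rng=rng)

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if self.downsample:
            x = x.avg_pool2d(2)
        h, w = x.shape[2], x.shape[3]
        if h < self.min_input or w < self.min_input:
            raise ValueError(
                f"critic input {h}x{w} below the minimum receptive field "
                f"({self.min_input}px{' after 2x downsampling' if self.downsample else ''})")
        y = self.conv1(x).leaky_relu(0.2)
        y = self.conv2(y).leaky_relu(0.2)
        return self.conv3(y)


def build_double_scale_discriminator(cfg: DiscriminatorConfig = None):
    """Return ``(global_critic, local_critic)``.

    The global critic scores a 2x-downsampled full image (overall blur
    distribution and context); the local critic scores full-resolution
    patches (fine texture).  For the same input the local score map is
    spatially larger.
    """
    cfg = cfg or DiscriminatorConfig()
    global_critic = PatchCritic(cfg, downsample=True, seed_offset=1)
    local_critic = PatchCritic(cfg, downsample=False, seed_offset=2)
    return global_critic, local_critic
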