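"""Lightweight FPN deblurring generator with a Ghost backbone and
Attention-Ghost / gated half-instance-normalization fusion modules.

The network maps a blurred RGB image to a residual correction that is added
back onto the input, so at initialization (and exactly, when the output
projection is zeroed) it is the identity.  Layout is NCHW in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np

from .autograd import Tensor, no_grad
from .nn import AGGBlock, Conv2d, GhostModule, Module, Sequential, count_parameters

__all__ = ["GeneratorConfig", "AggGenerator", "build_generator",
           "TINY_CONFIG", "count_parameters"]


@dataclass
class GeneratorConfig:
    """Architecture hyperparameters.

    Defaults reconstruct the published lightweight design: a stem plus four
    encoding stages at widths 16/24/40/80/160, 64/128-channel lateral
    projections, per-level two-layer Ghost heads to 64 channels, a
    256-channel multi-scale fusion tensor and an Attention-Ghost decoder
    ending in a 3-channel residual projection.
    """

    stage_widths: List[int] = field(default_factory=lambda: [16, 24, 40, 80, 160])
    lateral_shallow: int = 64
    lateral_deep: int = 128
    head_width: int = 64
    fused_width: int = 256
    decoder_mid_width: int = 256
    out_channels: int = 3
    blocks_per_stage: int = 2
    ghost_ratio: int = 2
    dw_kernel: int = 3
    se_reduction: int = 4
    encoder_primary_kernel: int = 3
    decoder_primary_kernel: int = 3
    pad_to_stride: bool = True  # reflect-pad inputs to a multiple of the stride
    seed: int = 0

    def validate(self):
        if len(self.stage_widths) != 5:
            raise ValueError("stage_widths must list five stage widths")
        if any(w <= 0 for w in self.stage_widths):
            raise ValueError("stage widths must be positive")


#: Reduced-width configuration for CPU-scale training experiments.
TINY_CONFIG = GeneratorConfig(
    stage_widths=[8, 12, 16, 24, 32],
    lateral_shallow=16,
    lateral_deep=32,
    head_width=16,
    fused_width=64,
    decoder_mid_width=32,
)


class _EncoderStage(Module):
    def __init__(self, in_ch, out_ch, cfg: GeneratorConfig, rng):
        blocks = [GhostModule(in_ch, out_ch, ratio=cfg.ghost_ratio,
                              primary_kernel=cfg.encoder_primary_kernel,
                              dw_kernel=cfg.dw_kernel, stride=2,
                              se_reduction=cfg.se_reduction, rng=rng)]
        for _ in range(cfg.blocks_per_stage - 1):
            blocks.append(GhostModule(out_ch, out_ch, ratio=cfg.ghost_ratio,
                                      primary_kernel=cfg.encoder_primary_kernel,
                                      dw_kernel=cfg.dw_kernel,
                                      se_reduction=cfg.se_reduction, rng=rng))
        self.blocks = blocks

    def forward(self, x):
        for b in self.blocks:
            x = b(x)
        return x


class _GhostHead(Module):
    """Two-layer Ghost head reducing a pyramid level to ``head_width``."""

    def __init__(self, in_ch, out_ch, cfg: GeneratorConfig, rng):
        self.net = Sequential(
            GhostModule(in_ch, in_ch, ratio=cfg.ghost_ratio,
                        primary_kernel=cfg.decoder_primary_kernel,
                        se_reduction=cfg.se_reduction, rng=rng),
            GhostModule(in_ch, out_ch, ratio=cfg.ghost_ratio,
                        primary_kernel=cfg.decoder_primary_kernel,
                        se_reduction=cfg.se_reduction, rng=rng),
        )

    def forward(self, x):
        return self.net(x)


class AggGenerator(Module):
    """Feature-pyramid Ghost generator with residual output."""

    total_stride = 16

    def __init__(self, cfg: GeneratorConfig = None):
        cfg = cfg or GeneratorConfig()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        w = cfg.stage_widths
        deep, shallow = cfg.lateral_deep, cfg.lateral_shallow

        self.stem = Conv2d(3, w[0], 3, padding=1, rng=rng)
        self.stages = [_EncoderStage(w[i], w[i + 1], cfg, rng) for i in range(4)]
        # 1x1 lateral projections: shallow width on the stem map, deep elsewhere
        self.lateral0 = Conv2d(w[0], shallow, 1, rng=rng)
        self.laterals = [Conv2d(w[i + 1], deep, 1, rng=rng) for i in range(4)]
        # three top-down fusions, each refined by an Attention-Ghost + GHIN pair
        self.td = [AGGBlock(deep, deep, primary_kernel=cfg.decoder_primary_kernel,
                            se_reduction=cfg.se_reduction, rng=rng)
                   for _ in range(3)]
        self.heads = [_GhostHead(deep, cfg.head_width, cfg, rng) for _ in range(4)]
        # decoder: fused 256-channel tensor -> AGG + upsample, twice
        self.agg_fuse1 = AGGBlock(cfg.fused_width, cfg.decoder_mid_width,
                                  primary_kernel=cfg.decoder_primary_kernel,
                                  se_reduction=cfg.se_reduction, rng=rng)
        self.agg_fuse2 = AGGBlock(cfg.decoder_mid_width, shallow,
                                  primary_kernel=cfg.decoder_primary_kernel,
                                  se_reduction=cfg.se_reduction, rng=rng)
        self.project = GhostModule(shallow, shallow, ratio=cfg.ghost_ratio,
                                   primary_kernel=cfg.decoder_primary_kernel,
                                   se_reduction=cfg.se_reduction, rng=rng)
        self.final = Conv2d(shallow, cfg.out_channels, 3, padding=1, rng=rng)
        # near-zero residual projection: the generator starts as ~identity
        self.final.weight.data *= 1e-2

    # -- geometry -------------------------------------------------------------
    def _pad_input(self, x: np.ndarray):
        s = self.total_stride
        n, c, h, w = x.shape
        ph = (-h) % s
        pw = (-w) % s
        if ph or pw:
            if not self.cfg.pad_to_stride:
                raise ValueError(
                    f"input spatial dims ({h}x{w}) must be multiples of {s}; "
                    "enable pad_to_stride or pad explicitly")
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
        return x, (h, w)

    def forward(self, x) -> Tensor:
        if isinstance(x, Tensor):
            data = x.data
        else:
            data = np.asarray(x, dtype=np.float32)
        padded, (h0, w0) = self._pad_input(data)
        inp = x if (isinstance(x, Tensor) and padded is data) else Tensor(padded)

        f = self.stem(inp)
        early = self.lateral0(f)              # 64ch, full resolution
        feats = []
        cur = f
        for stage in self.stages:
            cur = stage(cur)
            feats.append(cur)                 # strides 2, 4, 8, 16

        lat = [l(f_) for l, f_ in zip(self.laterals, feats)]
        # top-down pathway with AGG refinement
        p = lat[3]
        pyramid = [p]
        for td, l in zip(self.td, [lat[2], lat[1], lat[0]]):
            p = td(p.upsample_nearest2d(2) + l)
            pyramid.append(p)                 # strides 8, 4, 2

        # per-level heads, upsample to the shallowest pyramid level, concat
        heads = [h(p_) for h, p_ in zip(self.heads, pyramid)]
        factors = [8, 4, 2, 1]
        aligned = [hm.upsample_nearest2d(f_) if f_ > 1 else hm
                   for hm, f_ in zip(heads, factors)]
        fused = Tensor.cat(aligned, axis=1)   # 256ch at stride 2

        d = self.agg_fuse1(fused).upsample_nearest2d(2)   # mid width, stride 1
        d = self.agg_fuse2(d)                              # 64ch, stride 1
        d = d + early
        d = self.project(d)
        residual = self.final(d)
        out = (inp + residual).clamp(0.0, 1.0)
        if out.shape[2] != h0 or out.shape[3] != w0:
            out = Tensor._make(out.data[:, :, :h0, :w0], (out,),
                               lambda g: out._accum(_repad(g, out.shape)))
        return out

    def restore(self, image: np.ndarray) -> np.ndarray:
        """Deblur one HWC float image in [0, 1] (inference, no graph)."""
        x = np.asarray(image, dtype=np.float32).transpose(2, 0, 1)[None]
        with no_grad():
            y = self.forward(x)
        return y.data[0].transpose(1, 2, 0)

    def zero_output_projection(self):
        """Zero the final residual projection, making the network an exact identity."""
        self.final.weight.data[:] = 0.0
        self.final.bias.data[:] = 0.0


def _repad(g, shape):
    full = np.zeros(shape, dtype=np.float32)
    full[:, :, : g.shape[2], : g.shape[3]] = g
    return full


def build_generator(cfg: GeneratorConfig = None) -> AggGenerator:
    """Construct the generator from a :class:`GeneratorConfig`."""
    return AggGenerator(cfg)
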