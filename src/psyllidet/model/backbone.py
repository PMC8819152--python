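"""Parallel-resolution backbone with attention at fixed insertion sites.

The extractor keeps a high-resolution stream alive end to end: a two-conv
stem brings the input to 1/4 resolution, then three transitions add parallel
branches at 1/8, 1/16 and 1/32, and at the end of each multi-branch stage a
fusion unit exchanges information between all live branches (strided 3x3
convolutions downward, pointwise + nearest-upsample upward, elementwise sum).

Attention blocks sit at five fixed sites: one after each of the two stem
extraction convolutions (stage-1 extraction), and one on the fused
high-resolution map of the stage-2, stage-3 and stage-4 fusion units — the
stream whose preservation is the point of the parallel design.  Disabling
attention leaves every shape contract unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from ..nn import Conv2d, Module, Tensor
from .attention import CBAM

__all__ = ["BackboneConfig", "ImprovedBackbone", "build_improved_backbone"]


@dataclass(frozen=True)
class BackboneConfig:
    """Widths of the four branches plus attention hyperparameters.

    ``tiny`` selects a narrow test-scale variant that runs in seconds on one
    CPU; the default profile is wider but structurally identical.
    """

    widths: Tuple[int, int, int, int] = (32, 64, 128, 256)
    cbam_reduction: int = 16
    cbam_spatial_kernel: int = 7
    use_attention: bool = True
    tiny: bool = False

    @classmethod
    def make_tiny(cls, use_attention: bool = True) -> "BackboneConfig":
        return cls(
            widths=(8, 16, 32, 64),
            cbam_reduction=4,
            cbam_spatial_kernel=7,
            use_attention=use_attention,
            tiny=True,
        )

    def __post_init__(self) -> None:
        if len(self.widths) != 4:
            raise ValueError("exactly four branch widths are required")
        if any(w < 1 for w in self.widths):
            raise ValueError("branch widths must be positive")
        if self.use_attention:
            for w in self.widths:
                if w % self.cbam_reduction != 0:
                    raise ValueError(
                        f"branch width {w} not divisible by attention reduction "
                        f"{self.cbam_reduction}"
                    )


class _ConvBlock(Module):
    def __init__(self, c_in: int, c_out: int, rng, stride: int = 1):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, 3, stride=stride, padding=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x).relu()


class _FusionUnit(Module):
    """Exchange information among ``n`` live branches (all-to-all resample+sum)."""

    def __init__(self, widths: Tuple[int, ...], rng):
        super().__init__()
        self.n = len(widths)
        paths = []
        for i in range(self.n):          # target branch
            row = []
            for j in range(self.n):      # source branch
                if j == i:
                    row.append(None)
                elif j < i:  # finer -> coarser: strided conv
                    row.append(Conv2d(widths[j], widths[i], 3, stride=2 ** (i - j), padding=1, rng=rng))
                else:        # coarser -> finer: pointwise + upsample
                    row.append(Conv2d(widths[j], widths[i], 1, rng=rng))
            paths.append(row)
        # register submodules
        self._fusion_convs = [c for row in paths for c in row if c is not None]
        self.paths = paths

    def forward(self, xs: List[Tensor]) -> List[Tensor]:
        outs = []
        for i in range(self.n):
            acc = xs[i]
            for j in range(self.n):
                if j == i:
                    continue
                conv = self.paths[i][j]
                if j < i:
                    acc = acc + conv(xs[j])
                else:
                    acc = acc + conv(xs[j]).upsample_nearest(2 ** (j - i))
            outs.append(acc.relu())
        return outs


class ImprovedBackbone(Module):
    """Four-branch parallel-resolution feature extractor.

    Forward contract: an input of shape (N, 3, H, W) with H, W divisible by
    32 yields four maps at H/4, H/8, H/16 and H/32 with the configured widths.
    """

    def __init__(self, config: BackboneConfig, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        w = config.widths
        self.config = config

        def cbam(channels: int) -> Optional[CBAM]:
            if not config.use_attention:
                return None
            return CBAM(channels, config.cbam_reduction, config.cbam_spatial_kernel, rng=rng)

        # stage-1 extraction: two stride-2 convs, attention after each
        self.stem1 = _ConvBlock(3, w[0], rng, stride=2)
        self.stem_att1 = cbam(w[0])
        self.stem2 = _ConvBlock(w[0], w[0], rng, stride=2)
        self.stem_att2 = cbam(w[0])
        self.stage1_block = _ConvBlock(w[0], w[0], rng)

        # stage 2: branches (1/4, 1/8)
        self.trans1 = _ConvBlock(w[0], w[1], rng, stride=2)
        self.stage2_blocks = [_ConvBlock(w[0], w[0], rng), _ConvBlock(w[1], w[1], rng)]
        self.fuse2 = _FusionUnit(w[:2], rng)
        self.fuse2_att = cbam(w[0])

        # stage 3: branches (1/4, 1/8, 1/16)
        self.trans2 = _ConvBlock(w[1], w[2], rng, stride=2)
        self.stage3_blocks = [
            _ConvBlock(w[0], w[0], rng),
            _ConvBlock(w[1], w[1], rng),
            _ConvBlock(w[2], w[2], rng),
        ]
        self.fuse3 = _FusionUnit(w[:3], rng)
        self.fuse3_att = cbam(w[0])

        # stage 4: branches (1/4, 1/8, 1/16, 1/32)
        self.trans3 = _ConvBlock(w[2], w[3], rng, stride=2)
        self.stage4_blocks = [
            _ConvBlock(w[0], w[0], rng),
            _ConvBlock(w[1], w[1], rng),
            _ConvBlock(w[2], w[2], rng),
            _ConvBlock(w[3], w[3], rng),
        ]
        self.fuse4 = _FusionUnit(w, rng)
        self.fuse4_att = cbam(w[0])

    # -- audits -----------------------------------------------------------
    def attention_blocks(self) -> List[CBAM]:
        return [m for _, m in self.named_modules() if isinstance(m, CBAM)]

    def forward(self, x: Tensor) -> List[Tensor]:
        n, c, h, wdt = x.shape
        if h % 32 != 0 or wdt % 32 != 0:
            raise ValueError(f"input spatial dims must be divisible by 32, got {h}x{wdt}")

        def att(block: Optional[CBAM], t: Tensor) -> Tensor:
            return t if block is None else block(t)

        b0 = att(self.stem_att1, self.stem1(x))
        b0 = att(self.stem_att2, self.stem2(b0))
        b0 = self.stage1_block(b0)

        b1 = self.trans1(b0)
        b0 = self.stage2_blocks[0](b0)
        b1 = self.stage2_blocks[1](b1)
        b0, b1 = self.fuse2([b0, b1])
        b0 = att(self.fuse2_att, b0)

        b2 = self.trans2(b1)
        b0 = self.stage3_blocks[0](b0)
        b1 = self.stage3_blocks[1](b1)
        b2 = self.stage3_blocks[2](b2)
        b0, b1, b2 = self.fuse3([b0, b1, b2])
        b0 = att(self.fuse3_att, b0)

        b3 = self.trans3(b2)
        b0 = self.stage4_blocks[0](b0)
        b1 = self.stage4_blocks[1](b1)
        b2 = self.stage4_blocks[2](b2)
        b3 = self.stage4_blocks[3](b3)
        b0, b1, b2, b3 = self.fuse4([b0, b1, b2, b3])
        b0 = att(self.fuse4_att, b0)

        return [b0, b1, b2, b3]


def build_improved_backbone(
    config: BackboneConfig, rng: Optional[np.random.Generator] = None
) -> ImprovedBackbone:
    """Construct the attention-augmented parallel-resolution backbone."""
    return ImprovedBackbone(config, rng=rng)
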