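"""Convolutional block attention (CBAM): sequential channel + spatial gating.

Channel attention pools the feature map globally (average and max), pushes
both descriptors through a shared bottleneck MLP, sums and sigmoid-gates the
channels; spatial attention then pools across channels (mean and max),
convolves the 2-channel map with a large kernel and sigmoid-gates each
location.  Both gates lie strictly in (0, 1); with gates forced to one the
block is the identity, which is how the wiring is audited.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from ..nn import Conv2d, Linear, Module, Tensor, concat

__all__ = ["CBAM", "build_cbam"]


class CBAM(Module):
    def __init__(
        self,
        channels: int,
        reduction: int = 16,
        spatial_kernel: int = 7,
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        if channels % reduction != 0:
            raise ValueError(
                f"channels ({channels}) must be divisible by the reduction ratio ({reduction})"
            )
        if spatial_kernel % 2 != 1:
            raise ValueError("spatial kernel size must be odd")
        rng = rng if rng is not None else np.random.default_rng(0)
        hidden = channels // reduction
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)
        self.spatial_conv = Conv2d(2, 1, spatial_kernel, padding=spatial_kernel // 2, rng=rng)
        self.channels = channels
        self.force_gates_to_one = False  # audit hook: bypass both gates
        self.last_channel_gate: Optional[np.ndarray] = None
        self.last_spatial_gate: Optional[np.ndarray] = None

    def forward(self, x: Tensor) -> Tensor:
        if self.force_gates_to_one:
            self.last_channel_gate = None
            self.last_spatial_gate = None
            return x
        n, c, h, w = x.shape
        # channel gate
        avg = x.mean(axis=(2, 3))                       # (N, C)
        mx = x.reshape(n, c, h * w).max(axis=2)         # (N, C)
        att = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        cgate = att.sigmoid().reshape(n, c, 1, 1)
        x = x * cgate
        # spatial gate
        smean = x.mean(axis=1, keepdims=True)           # (N,1,H,W)
        smax = x.max(axis=1, keepdims=True)             # (N,1,H,W)
        sgate = self.spatial_conv(concat([smean, smax], axis=1)).sigmoid()
        out = x * sgate
        self.last_channel_gate = cgate.data
        self.last_spatial_gate = sgate.data
        return out


def build_cbam(
    channels: int,
    reduction: int = 16,
    spatial_kernel: int = 7,
    rng: Optional[np.random.Generator] = None,
) -> CBAM:
    """Construct a CBAM block for ``channels`` feature channels."""
    return CBAM(channels, reduction=reduction, spatial_kernel=spatial_kernel, rng=rng)
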