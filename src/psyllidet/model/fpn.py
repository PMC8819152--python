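"""Feature pyramid fusion of the four parallel-resolution branches.

Top-down pathway: each branch is projected to a uniform channel width by a
pointwise lateral convolution; starting from the coarsest level, features are
2x nearest-upsampled and added elementwise into the next finer lateral.  The
four outputs stay aligned to the input resolutions.  No smoothing
convolutions follow the sums, so a unit impulse injected at the coarsest
level propagates unblurred to every finer level — the property the wiring
test traces.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

from ..nn import Conv2d, Module, Tensor

__all__ = ["FPN", "build_fpn"]


class FPN(Module):
    def __init__(
        self,
        branch_channels: Sequence[int],
        out_channels: int = 16,
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        if len(branch_channels) != 4:
            raise ValueError(f"expected 4 input branches, got {len(branch_channels)}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.laterals = [Conv2d(c, out_channels, 1, rng=rng) for c in branch_channels]
        self.out_channels = out_channels

    def forward(self, branches: Sequence[Tensor]) -> List[Tensor]:
        if len(branches) != len(self.laterals):
            raise ValueError(
                f"expected {len(self.laterals)} branches, got {len(branches)}"
            )
        lats = [lat(b) for lat, b in zip(self.laterals, branches)]
        outs = [None] * len(lats)
        outs[-1] = lats[-1]
        for i in range(len(lats) - 2, -1, -1):
            outs[i] = lats[i] + outs[i + 1].upsample_nearest(2)
        return outs


def build_fpn(
    branch_channels: Sequence[int],
    out_channels: int = 16,
    rng: Optional[np.random.Generator] = None,
) -> FPN:
    """Top-down fusion module over exactly four branches."""
    return FPN(branch_channels, out_channels=out_channels, rng=rng)
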