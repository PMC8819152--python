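"""Sawtooth-rate atrous spatial pyramid pooling.

Parallel 3x3 dilated convolutions at increasing rates widen the receptive
field without losing resolution.  Large uniform rates such as (1, 3, 6, 12)
suit large objects but sample too sparsely for targets a few pixels wide and
produce gridding artifacts; the rates here follow a sawtooth/zigzag design,
default (1, 2, 5), in which consecutive rates share no common divisor > 1 so
the union of sampling positions covers the field densely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from ..nn import Conv2d, Module, Tensor, concat

__all__ = ["AsppConfig", "SawtoothAspp", "build_sawtooth_aspp", "validate_sawtooth_rates"]


def validate_sawtooth_rates(rates: Sequence[int]) -> None:
    """Reject rate sets that are not a valid sawtooth design.

    Rates must be integers >= 1, strictly increasing, and every consecutive
    pair must be coprime (a shared divisor > 1 reproduces the gridding
    artifact the zigzag layout exists to avoid).
    """
    if len(rates) < 1:
        raise ValueError("at least one dilation rate is required")
    for r in rates:
        if int(r) != r or r < 1:
            raise ValueError(f"dilation rates must be integers >= 1, got {r}")
    for a, b in zip(rates, rates[1:]):
        if b <= a:
            raise ValueError(f"dilation rates must be strictly increasing, got {a} then {b}")
        if math.gcd(int(a), int(b)) > 1:
            raise ValueError(
                f"consecutive dilation rates ({a}, {b}) share a common divisor "
                f"{math.gcd(int(a), int(b))} > 1, violating the sawtooth (gridding-free) design"
            )


@dataclass(frozen=True)
class AsppConfig:
    """Dilation rates and channel width of one per-branch pyramid."""

    dilation_rates: Tuple[int, ...] = (1, 2, 5)
    channels: int = 16

    def __post_init__(self) -> None:
        validate_sawtooth_rates(self.dilation_rates)
        if self.channels < 1:
            raise ValueError("channels must be positive")


class SawtoothAspp(Module):
    """One dilated 3x3 path per rate plus a pointwise path, concatenated and
    projected back to the branch width.  Spatial dims are preserved
    (padding = dilation)."""

    def __init__(self, config: AsppConfig, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        c = config.channels
        self.config = config
        self.pointwise = Conv2d(c, c, 1, rng=rng)
        self.dilated = [
            Conv2d(c, c, 3, padding=r, dilation=r, rng=rng) for r in config.dilation_rates
        ]
        self.project = Conv2d(c * (len(config.dilation_rates) + 1), c, 1, rng=rng)

    @property
    def n_paths(self) -> int:
        return len(self.dilated) + 1

    def forward(self, x: Tensor) -> Tensor:
        paths = [self.pointwise(x).relu()] + [conv(x).relu() for conv in self.dilated]
        return self.project(concat(paths, axis=1)).relu()


def build_sawtooth_aspp(config: AsppConfig, rng: Optional[np.random.Generator] = None) -> SawtoothAspp:
    """Construct the per-branch pyramid module (rates validated by the config)."""
    return SawtoothAspp(config, rng=rng)
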