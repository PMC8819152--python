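"""Cascade configuration and the weighted multi-stage training loss.

Three detection heads are trained at increasing IoU thresholds — each stage
refines the previous stage's boxes and is supervised against a stricter
definition of a positive — and their losses combine with fixed 1 : 0.5 : 0.25
weights into the total training loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

from ..nn import Tensor

__all__ = ["CascadeConfig", "cascade_total_loss"]


@dataclass(frozen=True)
class CascadeConfig:
    n_stages: int = 3
    stage_loss_weights: Tuple[float, ...] = (1.0, 0.5, 0.25)
    stage_iou_thresholds: Tuple[float, ...] = (0.5, 0.6, 0.7)

    def __post_init__(self) -> None:
        if self.n_stages != len(self.stage_loss_weights):
            raise ValueError("one loss weight per stage is required")
        if self.n_stages != len(self.stage_iou_thresholds):
            raise ValueError("one IoU threshold per stage is required")
        if any(w <= 0 for w in self.stage_loss_weights):
            raise ValueError("stage loss weights must be positive")
        t = self.stage_iou_thresholds
        if any(not (0.0 < x < 1.0) for x in t) or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("stage IoU thresholds must be strictly increasing in (0, 1)")


def cascade_total_loss(stage_losses: Sequence, weights: Tuple[float, ...] = (1.0, 0.5, 0.25)):
    """Weighted sum of per-stage losses, ``sum_i w_i * L_i``.

    Accepts plain numbers (returns a float) or autograd tensors (returns a
    tensor, so the weighting participates in backprop).  Negative numeric
    losses are rejected.
    """
    if len(stage_losses) != len(weights):
        raise ValueError("need exactly one weight per stage loss")
    if any(isinstance(l, Tensor) for l in stage_losses):
        total = None
        for w, l in zip(weights, stage_losses):
            term = l * w if isinstance(l, Tensor) else Tensor(float(l) * w)
            total = term if total is None else total + term
        return total
    for l in stage_losses:
        if l < 0:
            raise ValueError(f"stage losses must be non-negative, got {l}")
    return float(sum(w * l for w, l in zip(weights, stage_losses)))
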