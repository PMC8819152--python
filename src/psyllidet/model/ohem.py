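"""Online hard example mining: keep the highest-loss ROIs for training.

Random ROI sampling mostly draws easy negatives (open background), so a
detector never learns to reject the hard distractors — branches, stems and
withered leaves that share the pests' colour.  OHEM instead sorts the
per-ROI losses within each polarity and keeps the top 64 positives and top
192 negatives per batch per stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = ["RoiBatch", "ohem_sample"]


@dataclass
class RoiBatch:
    """Per-ROI loss values, polarity labels and stable indices."""

    losses: np.ndarray          # float, finite
    positive: np.ndarray        # bool
    indices: np.ndarray         # unique, stable identity of each ROI

    def __post_init__(self) -> None:
        self.losses = np.asarray(self.losses, dtype=float)
        self.positive = np.asarray(self.positive, dtype=bool)
        self.indices = np.asarray(self.indices)
        if not np.isfinite(self.losses).all():
            raise ValueError("ROI losses must be finite")
        if len({self.losses.shape, self.positive.shape, self.indices.shape}) != 1:
            raise ValueError("losses, polarity and indices must have equal length")
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("ROI indices must be unique")


def _top_by_loss(losses: np.ndarray, indices: np.ndarray, cap: int) -> np.ndarray:
    # descending loss, ties broken by ascending stable index
    order = np.lexsort((indices, -losses))
    return indices[order[: min(cap, len(indices))]]


def ohem_sample(batch: RoiBatch, n_pos: int = 64, n_neg: int = 192) -> Tuple[np.ndarray, np.ndarray]:
    """Select the ``n_pos`` highest-loss positive and ``n_neg`` highest-loss
    negative ROIs (all of a polarity when fewer exist than its cap).

    Returns ``(positive indices, negative indices)`` drawn from
    ``batch.indices``; selection is descending sort then prefix, with ties
    broken by stable index order.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("caps must be non-negative")
    pos = batch.positive
    pos_sel = _top_by_loss(batch.losses[pos], batch.indices[pos], n_pos)
    neg_sel = _top_by_loss(batch.losses[~pos], batch.indices[~pos], n_neg)
    return pos_sel, neg_sel
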