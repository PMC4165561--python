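"""Overlap metrics between predicted and ground-truth masks."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass(frozen=True)
class EvalReport:
    """Segmentation quality report.

    Dice and Jaccard satisfy ``dice = 2 * jaccard / (1 + jaccard)``; the
    Hausdorff distance (pixels) is omitted when either mask is empty.
    """

    dice: float
    jaccard: float
    hausdorff: Optional[float] = None
    iterations_run: Optional[int] = None
    method: Optional[str] = None
    params_echo: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "dice": self.dice,
            "jaccard": self.jaccard,
            "hausdorff": self.hausdorff,
            "iterations_run": self.iterations_run,
            "method": self.method,
            "params_echo": self.params_echo,
        }


def dice_jaccard(pred, truth) -> tuple[float, float]:
    """Dice ``2|A∩B|/(|A|+|B|)`` and Jaccard ``|A∩B|/|A∪B|``.

    Both equal 1.0 when both masks are empty (perfect agreement on
    nothing, the degenerate convention).
    """
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    inter = float(np.count_nonzero(pred & truth))
    a, b = float(np.count_nonzero(pred)), float(np.count_nonzero(truth))
    if a + b == 0:
        return 1.0, 1.0
    union = a + b - inter
    return 2.0 * inter / (a + b), inter / union if union else 1.0


def evaluate(pred, truth, iterations_run: Optional[int] = None, method: Optional[str] = None, params_echo: Optional[dict] = None) -> EvalReport:
    """Build a full report, including the Hausdorff distance if defined."""
    dice, jaccard = dice_jaccard(pred, truth)
    hausdorff = None
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.any() and truth.any():
        from skimage.metrics import hausdorff_distance

        hausdorff = float(hausdorff_distance(pred, truth))
    return EvalReport(
        dice=dice,
        jaccard=jaccard,
        hausdorff=hausdorff,
        iterations_run=iterations_run,
        method=method,
        params_echo=params_echo or {},
    )
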