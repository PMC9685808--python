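"""Segmentation scores for the diseased class: confusion counts, recall,
precision, F1, and the dice coefficient/loss.

Only the diseased class is scored — the quantity of interest is lesion
detection, and healthy/background pixels dominate every image. Undefined
ratios (zero denominator) are reported as NaN rather than 0 so dataset-level
averages can exclude degenerate images explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .io_formats import DISEASED, one_hot, validate_class_mask


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel counts for the diseased class."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ContractError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn
        )


def confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """TP/FP/FN of the diseased class between a predicted and a ground-truth
    class mask of equal shape."""
    pred = validate_class_mask(pred)
    gt = validate_class_mask(gt)
    if pred.shape != gt.shape:
        raise ContractError("prediction and ground truth shapes differ")
    p = pred == DISEASED
    g = gt == DISEASED
    return ConfusionCounts(
        tp=int((p & g).sum()), fp=int((p & ~g).sum()), fn=int((~p & g).sum())
    )


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN when the ground truth has no diseased pixels."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else math.nan


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); NaN when nothing was predicted diseased."""
    denom = c.tp + c.fp
    return c.tp / denom if denom else math.nan


def f1(c: ConfusionCounts) -> float:
    """TP / (TP + 0.5 (FP + FN)) — the harmonic mean of recall and precision;
    NaN when all three counts are zero."""
    denom = c.tp + 0.5 * (c.fp + c.fn)
    return c.tp / denom if denom else math.nan


def dice_coefficient(
    pred: np.ndarray, gt_mask: np.ndarray, epsilon: float = 1e-3
) -> float:
    """Smoothed dice coefficient over all pixels and classes.

        D = (2 sum(y y*) + eps) / (sum y + sum y* + eps)

    ``pred`` is an (H, W, 3) per-class probability map (rows summing to 1);
    ``gt_mask`` is a class mask, expanded to one-hot internally. D = 1 for a
    perfect prediction; the quantity minimized in training is 1 - D (see
    :func:`dice_loss`).
    """
    if epsilon <= 0:
        raise ContractError("epsilon must be positive")
    pred = np.asarray(pred, dtype=np.float64)
    gt = _as_probability(gt_mask)
    if pred.shape != gt.shape:
        raise ContractError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    if pred.min() < 0 or pred.max() > 1:
        raise ContractError("probabilities must lie in [0, 1]")
    sums = pred.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ContractError("per-pixel class scores must sum to 1")
    inter = float((pred * gt).sum())
    total = float(pred.sum() + gt.sum())
    return (2.0 * inter + epsilon) / (total + epsilon)


def dice_loss(pred: np.ndarray, gt_mask: np.ndarray, epsilon: float = 1e-3) -> float:
    """1 - dice coefficient (the training objective)."""
    return 1.0 - dice_coefficient(pred, gt_mask, epsilon)


def _as_probability(mask_or_prob: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask_or_prob)
    if arr.ndim == 2:
        return one_hot(arr)
    return arr.astype(np.float64)


def aggregate_scores(counts: list[ConfusionCounts]) -> dict[str, float]:
    """Dataset-level recall/precision/F1, both pooled over all pixels (micro)
    and averaged over per-image scores skipping NaNs (macro). The aggregation
    convention matters for skewed severity distributions, so both are given.
    """
    if not counts:
        raise ContractError("no confusion counts to aggregate")
    pooled = ConfusionCounts(0, 0, 0)
    for c in counts:
        pooled = pooled + c
    per_image = {
        "recall": [recall(c) for c in counts],
        "precision": [precision(c) for c in counts],
        "f1": [f1(c) for c in counts],
    }
    out = {
        "micro_recall": recall(pooled),
        "micro_precision": precision(pooled),
        "micro_f1": f1(pooled),
    }
    for name, vals in per_image.items():
        finite = [v for v in vals if not math.isnan(v)]
        out[f"macro_{name}"] = sum(finite) / len(finite) if finite else math.nan
    return out
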