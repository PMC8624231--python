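"""Segmentation overlap metrics and image-quality measures.

Dice scores follow the BraTS evaluation convention: three nested regions
(whole tumor = labels {1,2,4}, tumor core = {1,4}, enhancing = {4}) are each
scored as binary masks.  The multiclass soft dice loss

    L = -(2/K) * sum_k  [ sum_i l_ik m_ik / (sum_i l_ik + sum_i m_ik) ]

(l = per-class softmax scores, m = one-hot truth) is the class-imbalance
aware training objective; at perfect binary agreement every class term is
1/2 and L = -1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .core import LabelMap, Volume3D

__all__ = [
    "DiceInputs",
    "RegionMasks",
    "dice_score",
    "region_dice",
    "multiclass_dice_loss",
    "image_quality",
]


@dataclass
class RegionMasks:
    """The three nested BraTS evaluation regions of a label map."""

    whole: np.ndarray
    core: np.ndarray
    enhancing: np.ndarray

    @classmethod
    def from_labels(cls, lmap: LabelMap) -> "RegionMasks":
        lmap.validate_labels()
        return cls(whole=lmap.whole, core=lmap.core, enhancing=lmap.enhancing)


@dataclass
class DiceInputs:
    """Soft prediction scores and one-hot truth for the multiclass dice loss.

    Both arrays have the class axis last: shape (..., K).  Scores must sum
    to 1 across classes per voxel (softmax output); truth rows are one-hot.
    """

    soft_pred: np.ndarray
    one_hot_truth: np.ndarray

    def __post_init__(self) -> None:
        self.soft_pred = np.asarray(self.soft_pred, dtype=np.float64)
        self.one_hot_truth = np.asarray(self.one_hot_truth, dtype=np.float64)
        if self.soft_pred.shape != self.one_hot_truth.shape:
            raise ValueError("soft_pred and one_hot_truth shapes must agree")
        if self.soft_pred.ndim < 2:
            raise ValueError("expected shape (..., K) with at least one voxel axis")
        if np.any(self.soft_pred < 0) or np.any(self.soft_pred > 1):
            raise ValueError("soft_pred scores must lie in [0, 1]")
        if not np.allclose(self.soft_pred.sum(axis=-1), 1.0, atol=1e-6):
            raise ValueError("soft_pred must sum to 1 across classes per voxel")
        row = self.one_hot_truth.sum(axis=-1)
        if not np.all(row == 1.0) or not np.all(np.isin(self.one_hot_truth, (0.0, 1.0))):
            raise ValueError("one_hot_truth rows must be exactly one-hot")

    @property
    def num_classes(self) -> int:
        return self.soft_pred.shape[-1]


def dice_score(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Set dice 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    pred_mask = np.asarray(pred_mask, dtype=bool)
    true_mask = np.asarray(true_mask, dtype=bool)
    if pred_mask.shape != true_mask.shape:
        raise ValueError(f"shape mismatch: {pred_mask.shape} vs {true_mask.shape}")
    denom = int(pred_mask.sum()) + int(true_mask.sum())
    if denom == 0:
        return 1.0
    inter = int(np.count_nonzero(pred_mask & true_mask))
    return 2.0 * inter / denom


def region_dice(pred: LabelMap, truth: LabelMap) -> Tuple[float, float, float]:
    """Per-region dice (whole, core, enhancing) between two label maps."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    pm = RegionMasks.from_labels(pred)
    tm = RegionMasks.from_labels(truth)
    return (
        dice_score(pm.whole, tm.whole),
        dice_score(pm.core, tm.core),
        dice_score(pm.enhancing, tm.enhancing),
    )


def multiclass_dice_loss(inputs: DiceInputs) -> float:
    """Negative mean soft dice over classes, in [-1, 0].

    A class absent from both prediction and truth contributes 0 (no epsilon
    is added to the denominator).
    """
    l = inputs.soft_pred.reshape(-1, inputs.num_classes)
    m = inputs.one_hot_truth.reshape(-1, inputs.num_classes)
    num = (l * m).sum(axis=0)
    den = l.sum(axis=0) + m.sum(axis=0)
    terms = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return float(-(2.0 / inputs.num_classes) * terms.sum())


def image_quality(vol: Volume3D, reference: Volume3D, mask: np.ndarray = None):
    """Masked (RMSE, PSNR, mean-ratio) of a volume against a reference.

    PSNR uses the masked dynamic range of the reference as peak; it is +inf
    for identical inputs.  mean-ratio is masked mean(vol)/mean(reference).
    """
    if vol.shape != reference.shape:
        raise ValueError(f"shape mismatch: {vol.shape} vs {reference.shape}")
    if mask is None:
        mask = np.ones(vol.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != vol.shape:
            raise ValueError("mask shape mismatch")
    a = vol.data[mask]
    b = reference.data[mask]
    diff = a - b
    rmse = float(np.sqrt(np.mean(diff * diff)))
    peak = float(np.ptp(b))
    if rmse == 0:
        psnr = float("inf")
    elif peak == 0:
        psnr = float("-inf") if rmse > 0 else float("inf")
    else:
        psnr = float(20.0 * np.log10(peak / rmse))
    ref_mean = float(b.mean())
    mean_ratio = float(a.mean() / ref_mean) if ref_mean != 0 else float("nan")
    return rmse, psnr, mean_ratio
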