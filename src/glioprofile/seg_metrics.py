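"""Segmentation validation: pixelwise sweeps, patientwise detection,
pooled estimates across folds, and inter-rater consensus masks.

Pixelwise metrics (Dice, HD95) are computed on binarizations of a model's
probability map at ten equally spaced thresholds. Patientwise detection
treats each connected component as an object: small objects are discarded,
predictions are paired one-to-one to ground-truth tumors by overlap, and a
ground-truth tumor counts as detected when its pairing Dice reaches the
Dice threshold. Unpaired predictions are false positives (FPPP = false
positives per patient).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .volumes import (
    BinaryMask,
    EmptyMaskError,
    GeometryMismatchError,
    ProbabilityMap,
    connected_components,
    dice,
    hd95,
)

#: Default binarization thresholds: ten equally spaced bin centres in (0, 1),
#: avoiding the degenerate endpoints.
DEFAULT_THRESHOLDS = tuple(round(0.05 + 0.1 * i, 2) for i in range(10))
#: Objects below this voxel count are discarded before detection scoring.
MIN_OBJECT_VOXELS = 50
#: Pairing Dice required for a ground-truth tumor to count as detected.
DICE_DETECTION_THRESHOLD = 0.25


@dataclass
class PixelwiseResult:
    """Dice and HD95 per probability threshold (HD95 is NaN when undefined)."""

    thresholds: tuple[float, ...]
    dice: dict[float, float]
    hd95: dict[float, float]


def threshold_sweep(pred: ProbabilityMap, gt: BinaryMask,
                    thresholds: Sequence[float] = DEFAULT_THRESHOLDS
                    ) -> PixelwiseResult:
    """Binarize ``pred`` at each threshold (p >= t) and score against ``gt``.

    HD95 is undefined (NaN) whenever either mask is empty at a threshold.
    """
    if not pred.geometry.close_to(gt.geometry):
        raise GeometryMismatchError("prediction and ground truth geometries differ")
    dices: dict[float, float] = {}
    hds: dict[float, float] = {}
    for t in thresholds:
        binary = pred.binarize(t)
        dices[t] = dice(binary, gt)
        try:
            hds[t] = hd95(binary, gt)
        except EmptyMaskError:
            hds[t] = math.nan
    return PixelwiseResult(tuple(thresholds), dices, hds)


@dataclass
class PatientwiseResult:
    """Object-level detection outcome for one patient."""

    gt_detected: list[bool]           # true-positive flag per ground-truth tumor
    gt_dice: list[float]              # pairing Dice per ground-truth tumor (0 if unpaired)
    false_positive_count: int
    dice_tp: float                    # mean Dice over detected tumors (NaN if none)
    recall: float                     # NaN when no ground-truth tumors
    precision: float                  # NaN when no predictions
    f1: float
    fppp: int

    @property
    def true_positive_count(self) -> int:
        return sum(self.gt_detected)


def _harmonic(r: float, p: float) -> float:
    if math.isnan(r) or math.isnan(p):
        return math.nan
    if r + p == 0:
        return 0.0
    return 2 * r * p / (r + p)


def patientwise_detection(pred: BinaryMask, gt: BinaryMask,
                          dice_threshold: float = DICE_DETECTION_THRESHOLD,
                          min_voxels: int = MIN_OBJECT_VOXELS,
                          connectivity: int = 26) -> PatientwiseResult:
    """Object-level detection scoring of a prediction against ground truth.

    Components of either mask below ``min_voxels`` are discarded. Each
    ground-truth tumor is greedily paired to the overlapping prediction
    component of largest overlap, one-to-one (ties broken by component
    label order); it is a true positive when the pairing Dice reaches
    ``dice_threshold``. Prediction components left unpaired are false
    positives.
    """
    if not pred.geometry.close_to(gt.geometry):
        raise GeometryMismatchError("prediction and ground truth geometries differ")

    def _objects(mask: BinaryMask) -> list[np.ndarray]:
        comps = connected_components(mask, connectivity)
        return [comps.labels == lab
                for lab in range(1, comps.count + 1)
                if comps.sizes[lab - 1] >= min_voxels]

    gt_objs = _objects(gt)
    pred_objs = _objects(pred)

    # all candidate (overlap, gt index, pred index) pairs, greedy descending
    candidates = []
    for gi, g in enumerate(gt_objs):
        for pi, p in enumerate(pred_objs):
            inter = int(np.logical_and(g, p).sum())
            if inter > 0:
                candidates.append((inter, gi, pi))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))

    paired_gt: dict[int, int] = {}
    used_pred: set[int] = set()
    for inter, gi, pi in candidates:
        if gi in paired_gt or pi in used_pred:
            continue
        paired_gt[gi] = pi
        used_pred.add(pi)

    detected: list[bool] = []
    gt_dice: list[float] = []
    for gi, g in enumerate(gt_objs):
        if gi in paired_gt:
            p = pred_objs[paired_gt[gi]]
            inter = int(np.logical_and(g, p).sum())
            d = 2.0 * inter / (int(g.sum()) + int(p.sum()))
        else:
            d = 0.0
        gt_dice.append(d)
        detected.append(d >= dice_threshold)

    # false positives are the prediction components left without a pairing;
    # a paired prediction below the Dice threshold is a missed detection,
    # not an erroneous extra object
    fp = len(pred_objs) - len(used_pred)
    tp = sum(detected)

    recall = tp / len(gt_objs) if gt_objs else math.nan
    precision = tp / len(pred_objs) if pred_objs else math.nan
    tp_dices = [d for d, det in zip(gt_dice, detected) if det]
    dice_tp = float(np.mean(tp_dices)) if tp_dices else math.nan
    return PatientwiseResult(detected, gt_dice, fp, dice_tp, recall, precision,
                             _harmonic(recall, precision), fp)


@dataclass
class PooledEstimate:
    """Size-weighted pooled mean/SD of one metric across validation folds.

    With fold sizes n_i, means m_i and SDs s_i (ddof=1):

        N  = sum n_i
        M  = sum n_i * m_i / N
        S² = [ sum (n_i − 1) s_i² + sum n_i (m_i − M)² ] / (N − 1)

    which equals the sample mean/SD of the concatenated per-patient values.
    """

    mean: float
    std: float
    fold_means: list[float] = field(default_factory=list)
    fold_stds: list[float] = field(default_factory=list)
    fold_sizes: list[int] = field(default_factory=list)


def pooled_estimates(fold_means: Sequence[float], fold_stds: Sequence[float],
                     fold_sizes: Sequence[int]) -> PooledEstimate:
    """Pool per-fold summaries into a cohort-level mean and SD."""
    if not len(fold_means):
        raise ValueError("at least one fold is required")
    if not (len(fold_means) == len(fold_stds) == len(fold_sizes)):
        raise ValueError("fold summaries must have equal lengths")
    m = np.asarray(fold_means, float)
    s = np.asarray(fold_stds, float)
    n = np.asarray(fold_sizes, int)
    if (n < 1).any():
        raise ValueError("fold sizes must be positive")
    total = int(n.sum())
    mean = float((n * m).sum() / total)
    if total > 1:
        var = (((n - 1) * s ** 2).sum() + (n * (m - mean) ** 2).sum()) / (total - 1)
        std = float(np.sqrt(var))
    else:
        std = float(s[0])
    return PooledEstimate(mean, std, list(map(float, m)), list(map(float, s)),
                          list(map(int, n)))


def consensus_mask(rater_masks: Sequence[BinaryMask]) -> BinaryMask:
    """Majority-vote consensus: a voxel is foreground iff annotated by at
    least half of the raters (>= R/2, so 4 of 8 suffice)."""
    if len(rater_masks) < 2:
        raise ValueError("consensus requires at least two raters")
    first = rater_masks[0]
    for m in rater_masks[1:]:
        if not m.geometry.close_to(first.geometry):
            raise GeometryMismatchError("rater masks do not share a geometry")
    votes = np.sum([m.data for m in rater_masks], axis=0)
    return BinaryMask(first.geometry, votes >= len(rater_masks) / 2.0)
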