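"""Voxel-overlap evaluation metrics for binary and multi-label masks."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from .volumes_io import ARTERY_LABELS, ArteryLabelMap


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int


@dataclass(frozen=True)
class MetricPanel:
    """Dice, Jaccard, volumetric similarity, sensitivity, precision.

    ``both_empty`` flags the degenerate case where prediction and ground
    truth are both empty; all metrics are then 1.0 by convention.
    """

    dice: float
    jaccard: float
    volumetric_similarity: float
    sensitivity: float
    precision: float
    both_empty: bool = False

    def as_dict(self) -> Dict[str, float]:
        return {
            "dice": self.dice,
            "jaccard": self.jaccard,
            "vs": self.volumetric_similarity,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
        }


def _as_bool(a) -> np.ndarray:
    return np.asarray(a) != 0


def confusion(pred, gt) -> ConfusionCounts:
    """Voxelwise confusion counts between two binary masks."""
    p, g = _as_bool(pred), _as_bool(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def panel_from_counts(c: ConfusionCounts) -> MetricPanel:
    tp, fp, fn = c.tp, c.fp, c.fn
    if tp + fp + fn == 0:
        return MetricPanel(1.0, 1.0, 1.0, 1.0, 1.0, both_empty=True)
    dice = 2 * tp / (2 * tp + fp + fn)
    jaccard = tp / (tp + fp + fn)
    vs = 1.0 - abs(fp - fn) / (2 * tp + fp + fn)
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    return MetricPanel(dice, jaccard, vs, sensitivity, precision)


def metric_panel(pred, gt) -> MetricPanel:
    """Evaluate a predicted binary mask against ground truth.

    dice = 2tp/(2tp+fp+fn); jaccard = tp/(tp+fp+fn);
    vs = 1 - |fp-fn|/(2tp+fp+fn); sensitivity = tp/(tp+fn);
    precision = tp/(tp+fp).  Both masks empty -> all 1.0, flagged.
    """
    return panel_from_counts(confusion(pred, gt))


def per_region_panels(pred, gt) -> Dict[str, MetricPanel]:
    """One metric panel per artery region (labels 1-4).

    Accepts ArteryLabelMap / ShortenedLabelMap instances or raw integer
    grids on a shared grid.
    """
    p = pred.grid if hasattr(pred, "grid") else np.asarray(pred)
    g = gt.grid if hasattr(gt, "grid") else np.asarray(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    return {
        name: metric_panel(p == label, g == label)
        for label, name in ARTERY_LABELS.items()
    }
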