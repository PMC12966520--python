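"""Threshold-based calcification segmentation baselines.

Two reference methods: an idealized per-case search that picks the
global threshold maximizing Dice against ground truth, and a clinically
realistic fixed threshold (default 470 HU) derived as the mean of
per-case optima over a training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .seg_metrics import metric_panel
from .volumes_io import CalcMask, HUVolume


@dataclass(frozen=True)
class ClinicalThresholdConfig:
    """Fixed global threshold of the clinically realistic method."""

    threshold_hu: float = 470.0

    def __post_init__(self):
        if not np.isfinite(self.threshold_hu):
            raise ValueError("threshold must be finite")


@dataclass
class ThresholdSearchResult:
    best_threshold: float
    best_dice: float
    candidates: List[Tuple[float, float]]


def _hu_grid(hu) -> np.ndarray:
    return hu.grid if isinstance(hu, HUVolume) else np.asarray(hu)


def _mask_of(m) -> np.ndarray:
    return (m.grid if hasattr(m, "grid") else np.asarray(m)) != 0


def apply_threshold(hu, roi, threshold: float) -> np.ndarray:
    """Binary mask of ROI voxels with intensity >= threshold.

    Voxels outside the ROI are always background.
    """
    grid = _hu_grid(hu)
    roi = _mask_of(roi)
    if grid.shape != roi.shape:
        raise ValueError(f"shape mismatch: {grid.shape} vs {roi.shape}")
    if not roi.any():
        raise ValueError("ROI is empty")
    return roi & (grid >= threshold)


def candidate_thresholds(
    hu, roi, step_fraction: float = 0.01, strategy: str = "range"
) -> np.ndarray:
    """Threshold grid for the idealized search.

    ``range``: linear between ROI min and max HU at ``step_fraction``
    intervals (101 candidates at the default 1%).  ``percentile``:
    intensity percentiles of the ROI at the same fractional steps.
    """
    grid = _hu_grid(hu)
    vals = grid[_mask_of(roi)]
    n = int(round(1.0 / step_fraction))
    fracs = np.arange(n + 1) / n
    if strategy == "range":
        lo, hi = float(vals.min()), float(vals.max())
        return lo + fracs * (hi - lo)
    if strategy == "percentile":
        return np.percentile(vals, fracs * 100.0)
    raise ValueError(f"unknown strategy {strategy!r}")


def optimal_threshold(
    hu,
    roi,
    gt_calc,
    step_fraction: float = 0.01,
    strategy: str = "range",
) -> ThresholdSearchResult:
    """Idealized per-case search: the threshold maximizing Dice vs GT.

    Ties are broken toward the lowest threshold.  Requires ground truth,
    so it is a best-case reference, not a clinical method.
    """
    grid = _hu_grid(hu)
    roi = _mask_of(roi)
    gt = _mask_of(gt_calc)
    if not roi.any():
        raise ValueError("ROI is empty")
    if not gt.any():
        raise ValueError("ground-truth calcification mask is empty; "
                         "Dice is degenerate for every threshold")
    vals = grid[roi]
    if vals.min() == vals.max():
        raise ValueError("constant-intensity ROI; threshold search is degenerate")
    cands = candidate_thresholds(grid, roi, step_fraction, strategy)
    pairs: List[Tuple[float, float]] = []
    best_t, best_d = None, -1.0
    for t in cands:
        pred = roi & (grid >= t)
        d = metric_panel(pred, gt).dice
        pairs.append((float(t), float(d)))
        if d > best_d:
            best_t, best_d = float(t), float(d)
    return ThresholdSearchResult(best_threshold=best_t, best_dice=best_d,
                                 candidates=pairs)


def mean_optimal_threshold(
    cases: Sequence[Tuple[object, object, object]],
    step_fraction: float = 0.01,
    strategy: str = "range",
) -> float:
    """Mean of per-case optimal thresholds over (hu, roi, gt) cases."""
    if not cases:
        raise ValueError("need at least one case")
    optima = [
        optimal_threshold(hu, roi, gt, step_fraction, strategy).best_threshold
        for hu, roi, gt in cases
    ]
    return float(np.mean(optima))


# Tested-and-rejected alternatives; hooks only, intentionally not implemented.
def otsu_threshold(hu, roi):  # pragma: no cover
    raise NotImplementedError("Otsu variant is out of scope")


def percentile_threshold(hu, roi, percentile):  # pragma: no cover
    raise NotImplementedError("highest-HU-percentile variant is out of scope")
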