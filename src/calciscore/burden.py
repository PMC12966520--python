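"""Volume-normalized calcification burden scoring per artery group.

Burden for a group = calcified volume inside the group's shortened
artery mask / artery volume, bounded in [0, 1].  Cluster morphology
(count, mean size in mm^3) uses 6-connected components assigned to the
group of majority overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes_io import ARTERY_LABELS, GROUP_NAMES, Spacing3D

logger = logging.getLogger(__name__)

# tie-break priority for cluster assignment
_PRIORITY = {"aorta": 0, "iliac": 1, "mesenteric": 2, "renal": 3}


@dataclass
class CalcCluster:
    mask: np.ndarray
    size_mm3: float

    @property
    def voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class GroupScore:
    group: str
    artery_volume_mm3: float
    calc_volume_mm3: float
    burden: Optional[float]  # None when artery volume is zero
    cluster_count: int
    mean_cluster_size_mm3: Optional[float]  # None when no clusters


@dataclass
class GroupScores:
    per_group: Dict[str, GroupScore]

    def __getitem__(self, group: str) -> GroupScore:
        return self.per_group[group]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": s.group,
                "artery_volume_mm3": s.artery_volume_mm3,
                "calc_volume_mm3": s.calc_volume_mm3,
                "burden": s.burden if s.burden is not None else float("nan"),
                "cluster_count": s.cluster_count,
                "mean_cluster_size_mm3": (
                    s.mean_cluster_size_mm3
                    if s.mean_cluster_size_mm3 is not None else float("nan")
                ),
            }
            for s in self.per_group.values()
        ]
        return pd.DataFrame(rows)


def _grid_of(x) -> np.ndarray:
    return x.grid if hasattr(x, "grid") else np.asarray(x)


def _spacing_of(x, default=1.0) -> Spacing3D:
    return x.spacing if hasattr(x, "spacing") else Spacing3D.make(default)


def calc_clusters(calc, connectivity: int = 6) -> List[CalcCluster]:
    """Connected components of the calcification mask with sizes in mm^3."""
    grid = _grid_of(calc) != 0
    spacing = _spacing_of(calc)
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    structure = ndimage.generate_binary_structure(3, rank)
    labelled, n = ndimage.label(grid, structure=structure)
    vol = spacing.voxel_volume_mm3
    clusters = []
    for i in range(1, n + 1):
        mask = labelled == i
        clusters.append(CalcCluster(mask=mask, size_mm3=float(mask.sum()) * vol))
    return clusters


def assign_clusters(
    clusters: List[CalcCluster], shortened
) -> Dict[str, List[CalcCluster]]:
    """Assign each cluster to the artery group of majority voxel overlap.

    Zero-overlap clusters (e.g. on trimmed-away distal vessel) are
    discarded and logged.  Overlap ties go to the higher-priority group
    (aorta > iliac > mesenteric > renal).
    """
    labels = _grid_of(shortened)
    assigned: Dict[str, List[CalcCluster]] = {g: [] for g in GROUP_NAMES}
    for cluster in clusters:
        overlaps = {
            name: int(np.count_nonzero(cluster.mask & (labels == lab)))
            for lab, name in ARTERY_LABELS.items()
        }
        best = max(overlaps.items(),
                   key=lambda kv: (kv[1], -_PRIORITY[kv[0]]))
        if best[1] == 0:
            logger.info("discarding cluster of %.1f mm^3 outside all arteries",
                        cluster.size_mm3)
            continue
        assigned[best[0]].append(cluster)
    return assigned


def cluster_stats(assigned: Dict[str, List[CalcCluster]]):
    """Per-group (cluster count, mean cluster size mm^3); mean is None at 0."""
    out = {}
    for group, clusters in assigned.items():
        count = len(clusters)
        total = sum(c.size_mm3 for c in clusters)
        out[group] = (count, total / count if count else None)
    return out


def burden_scores(calc, shortened, connectivity: int = 6) -> GroupScores:
    """Full per-group burden scoring.

    Numerator calc volume per group is clipped to that group's artery
    mask, guaranteeing burden <= 1.  The combined score pools the four
    groups volume-wise: sum(calc) / sum(artery).
    """
    labels = _grid_of(shortened)
    calc_grid = _grid_of(calc) != 0
    if labels.shape != calc_grid.shape:
        raise ValueError(
            f"shape mismatch: {labels.shape} vs {calc_grid.shape}")
    spacing = _spacing_of(shortened)
    voxvol = spacing.voxel_volume_mm3

    clusters = calc_clusters(calc, connectivity=connectivity)
    assigned = assign_clusters(clusters, shortened)
    stats = cluster_stats(assigned)

    per_group: Dict[str, GroupScore] = {}
    tot_calc = 0.0
    tot_artery = 0.0
    for lab, name in ARTERY_LABELS.items():
        group_mask = labels == lab
        artery_vol = float(group_mask.sum()) * voxvol
        clipped = 0
        for cluster in assigned[name]:
            clipped += int(np.count_nonzero(cluster.mask & group_mask))
        calc_vol = clipped * voxvol
        burden = calc_vol / artery_vol if artery_vol > 0 else None
        count, mean_size = stats[name]
        per_group[name] = GroupScore(
            group=name, artery_volume_mm3=artery_vol, calc_volume_mm3=calc_vol,
            burden=burden, cluster_count=count, mean_cluster_size_mm3=mean_size)
        tot_calc += calc_vol
        tot_artery += artery_vol

    combined_clusters = sum(len(assigned[g]) for g in GROUP_NAMES)
    assigned_total = sum(c.size_mm3 for g in GROUP_NAMES for c in assigned[g])
    per_group["combined"] = GroupScore(
        group="combined",
        artery_volume_mm3=tot_artery,
        calc_volume_mm3=tot_calc,
        burden=tot_calc / tot_artery if tot_artery > 0 else None,
        cluster_count=combined_clusters,
        mean_cluster_size_mm3=(
            assigned_total / combined_clusters if combined_clusters else None),
    )
    return GroupScores(per_group=per_group)
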