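"""Vessel-tree length standardization.

Trims each side artery (iliac, mesenteric, renal) to a fixed length
measured geodesically from its aortic stump, then truncates the aorta a
fixed margin above the highest retained side artery.  All steps run on a
1 mm isotropic working grid.

Pipeline: resample -> side-branch connected components -> per-component
stump definition and geodesic regrowth -> label reassembly -> aorta
truncation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List

import numpy as np
from scipy import ndimage

from .volumes_io import ArteryLabelMap, Spacing3D

logger = logging.getLogger(__name__)

SIDE_LABELS = (2, 3, 4)


def _structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}
    if connectivity not in rank:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    return ndimage.generate_binary_structure(3, rank[connectivity])


@dataclass(frozen=True)
class ShorteningConfig:
    """Parameters of the shortening algorithm (defaults match the method)."""

    target_length_mm: float = 25.0
    n_dilations: int = 25
    aorta_dilations_for_stump: int = 2
    aorta_margin_mm: float = 10.0
    stump_gap_mm: float = 25.0
    connectivity: int = 6
    working_spacing_mm: float = 1.0
    on_no_side_arteries: str = "error"  # or "passthrough"

    def __post_init__(self):
        for name in ("target_length_mm", "aorta_margin_mm", "stump_gap_mm",
                     "working_spacing_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_dilations < 1:
            raise ValueError("n_dilations must be >= 1")
        _structure(self.connectivity)

    @property
    def structure(self) -> np.ndarray:
        return _structure(self.connectivity)


@dataclass
class SideComponent:
    """One connected component of a single side-artery label."""

    label: int
    mask: np.ndarray

    @property
    def size(self) -> int:
        return int(self.mask.sum())


@dataclass
class ComponentLog:
    label: int
    component_voxels: int
    stump_voxels: int
    grown_voxels: int
    removed_islets: int
    dilations_run: int
    detached: bool = False


@dataclass
class ShortenedLabelMap:
    """Shortened artery map on the isotropic working grid, with provenance."""

    grid: np.ndarray
    spacing: Spacing3D
    config: ShorteningConfig
    component_logs: List[ComponentLog] = field(default_factory=list)

    def as_label_map(self) -> ArteryLabelMap:
        return ArteryLabelMap(grid=self.grid, spacing=self.spacing)

    def mask(self, label: int) -> np.ndarray:
        return self.grid == label


def find_side_components(
    arteries: ArteryLabelMap, cfg: ShorteningConfig = ShorteningConfig()
) -> List[SideComponent]:
    """Connected components of the side arteries, one label at a time.

    Components are returned in deterministic order: by label, then by
    size descending, then by first-voxel index.
    """
    structure = cfg.structure
    out: List[SideComponent] = []
    for label in SIDE_LABELS:
        binary = arteries.grid == label
        if not binary.any():
            continue
        labelled, n = ndimage.label(binary, structure=structure)
        comps = []
        for i in range(1, n + 1):
            mask = labelled == i
            comps.append(SideComponent(label=label, mask=mask))
        comps.sort(key=lambda c: (-c.size, np.argmax(c.mask.ravel())))
        out.extend(comps)
    return out


def _min_gap_mm(a: np.ndarray, b: np.ndarray, spacing_mm: float) -> float:
    """Minimal surface-to-surface distance between two disjoint masks.

    Computed as the minimal voxel-centre Euclidean distance minus one
    voxel (surfaces sit half a voxel from each centre), clipped at 0.
    """
    dist = ndimage.distance_transform_edt(~a, sampling=(spacing_mm,) * 3)
    centre = float(dist[b].min())
    return max(centre - spacing_mm, 0.0)


def define_stump(
    component: np.ndarray,
    aorta: np.ndarray,
    cfg: ShorteningConfig = ShorteningConfig(),
) -> np.ndarray:
    """Seed region of a side branch: its overlap with the dilated aorta.

    The aorta is dilated ``cfg.aorta_dilations_for_stump`` times and
    intersected with the component.  Sub-components of that intersection
    lying more than ``cfg.stump_gap_mm`` from the largest one are dropped;
    the rest are merged.  An empty intersection marks the component as
    detached (empty stump returned).
    """
    if not aorta.any():
        raise ValueError("aorta mask is empty")
    structure = cfg.structure
    dilated = ndimage.binary_dilation(
        aorta, structure=structure, iterations=cfg.aorta_dilations_for_stump
    )
    stump = component & dilated
    if not stump.any():
        return stump
    labelled, n = ndimage.label(stump, structure=structure)
    if n == 1:
        return stump
    sizes = ndimage.sum_labels(stump, labelled, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    keep = labelled == largest
    spacing = cfg.working_spacing_mm
    for i in range(1, n + 1):
        if i == largest:
            continue
        islet = labelled == i
        if _min_gap_mm(keep, islet, spacing) <= cfg.stump_gap_mm:
            keep = keep | islet
    return keep


def grow_stump(
    stump: np.ndarray,
    component: np.ndarray,
    cfg: ShorteningConfig = ShorteningConfig(),
) -> np.ndarray:
    """Geodesic regrowth of a stump inside its component.

    Iteratively dilates the stump, masking to the component after every
    single-voxel dilation, for ``cfg.n_dilations`` iterations — i.e. the
    set of component voxels within geodesic distance ``n_dilations`` of
    the stump.
    """
    grown, _ = _grow(stump, component, cfg)
    return grown


def _grow(stump: np.ndarray, component: np.ndarray, cfg: ShorteningConfig):
    if not stump.any():
        return stump.copy(), 0
    if not np.all(component[stump]):
        raise ValueError("stump must be a subset of its component")
    structure = cfg.structure
    grown = stump.copy()
    iterations = 0
    for _ in range(cfg.n_dilations):
        nxt = ndimage.binary_dilation(grown, structure=structure) & component
        iterations += 1
        if np.array_equal(nxt, grown):  # saturated: whole component reached
            break
        grown = nxt
    return grown, iterations


def truncate_aorta(
    aorta: np.ndarray,
    shortened_sides: np.ndarray,
    cfg: ShorteningConfig = ShorteningConfig(),
) -> np.ndarray:
    """Remove aorta voxels more than the margin above the highest side artery.

    ``shortened_sides`` is any array where nonzero marks side-artery
    voxels.  Axis 2 is superior; the cut plane sits ``aorta_margin_mm``
    above the most superior side-artery voxel.
    """
    side = np.asarray(shortened_sides) != 0
    if not side.any():
        if cfg.on_no_side_arteries == "passthrough":
            logger.warning("no side arteries present; aorta left untouched")
            return aorta.copy()
        raise ValueError("no side arteries present; cannot place the cut plane")
    z_side = int(np.max(np.nonzero(side.any(axis=(0, 1)))[0]))
    margin_slices = int(round(cfg.aorta_margin_mm / cfg.working_spacing_mm))
    out = aorta.copy()
    out[:, :, z_side + margin_slices + 1:] = False
    return out


def shorten(
    arteries: ArteryLabelMap, cfg: ShorteningConfig = ShorteningConfig()
) -> ShortenedLabelMap:
    """Run the full shortening pipeline on an artery label map."""
    from .volumes_io import resample_isotropic

    if not (arteries.grid == 1).any():
        raise ValueError("input label map contains no aorta (label 1)")
    iso = resample_isotropic(arteries, cfg.working_spacing_mm)
    aorta = iso.grid == 1
    components = find_side_components(iso, cfg)

    out = np.zeros_like(iso.grid)
    logs: List[ComponentLog] = []
    for comp in components:
        stump = define_stump(comp.mask, aorta, cfg)
        if not stump.any():
            logs.append(ComponentLog(comp.label, comp.size, 0, 0, 0, 0,
                                     detached=True))
            logger.info("label %d component (%d voxels): detached, removed",
                        comp.label, comp.size)
            continue
        # islet count: raw-intersection sub-components minus retained ones
        raw = comp.mask & ndimage.binary_dilation(
            aorta, structure=cfg.structure,
            iterations=cfg.aorta_dilations_for_stump)
        _, n_raw = ndimage.label(raw, structure=cfg.structure)
        _, n_kept = ndimage.label(stump, structure=cfg.structure)
        grown, iters = _grow(stump, comp.mask, cfg)
        out[grown] = comp.label
        logs.append(ComponentLog(comp.label, comp.size, int(stump.sum()),
                                 int(grown.sum()), n_raw - n_kept, iters))
        logger.info("label %d component: stump %d, grown %d voxels, "
                    "%d dilations", comp.label, int(stump.sum()),
                    int(grown.sum()), iters)

    sides = out != 0
    if sides.any():
        aorta_out = truncate_aorta(aorta, sides, cfg)
    elif cfg.on_no_side_arteries == "passthrough":
        aorta_out = aorta
    else:
        raise ValueError("no side arteries survived shortening")
    out[aorta_out] = 1
    return ShortenedLabelMap(
        grid=out.astype(np.uint8),
        spacing=Spacing3D.make(cfg.working_spacing_mm),
        config=cfg,
        component_logs=logs,
    )
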