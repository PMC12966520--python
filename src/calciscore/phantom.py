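"""Synthetic CTA phantoms: HU volume + artery labels + calcification mask.

Phantoms are built on an isotropic grid (1 mm default): a vertical
cylindrical aorta (label 1), straight or bent side branches (labels
2/3/4) attached orthogonally, and ellipsoidal/spherical calcified
lesions rasterized into both the calcification mask and the HU bands.
Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .volumes_io import (
    ARTERY_LABELS,
    GROUP_NAMES,
    ArteryLabelMap,
    CalcMask,
    HUVolume,
    Spacing3D,
)

_DIRECTIONS = {
    "+x": np.array([1.0, 0.0, 0.0]),
    "-x": np.array([-1.0, 0.0, 0.0]),
    "+y": np.array([0.0, 1.0, 0.0]),
    "-y": np.array([0.0, -1.0, 0.0]),
}


@dataclass(frozen=True)
class BranchSpec:
    """One side branch: label, attachment slice, direction, length.

    ``length_mm`` is measured beyond the aortic surface.  ``bend_deg``
    turns the branch tangent toward superior at a constant rate over its
    length (0 = straight), for geodesic-growth testing.
    """

    label: int
    attach_z: int
    direction: str
    length_mm: float
    bend_deg: float = 0.0

    def __post_init__(self):
        if self.label not in (2, 3, 4):
            raise ValueError("branch label must be 2, 3, or 4")
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {sorted(_DIRECTIONS)}")
        if self.length_mm <= 0:
            raise ValueError("branch length must be positive")


@dataclass(frozen=True)
class LesionSpec:
    """Spherical calcified lesion; centre in voxel coordinates."""

    center: Tuple[float, float, float]
    radius_mm: float
    host_label: int  # artery label the lesion lives in

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be positive")
        if self.host_label not in (1, 2, 3, 4):
            raise ValueError("host label must be 1..4")


@dataclass
class PhantomConfig:
    grid_shape: Tuple[int, int, int] = (160, 160, 96)
    spacing: float = 1.0
    aorta_center: Optional[Tuple[float, float]] = None  # default: grid centre
    aorta_radius_mm: float = 8.0
    aorta_z_range: Optional[Tuple[int, int]] = None  # inclusive; default: full
    branch_radius_mm: float = 3.0
    branch_specs: Sequence[BranchSpec] = field(default_factory=tuple)
    lesions: Sequence[LesionSpec] = field(default_factory=tuple)
    lumen_hu_mean: float = 300.0
    lumen_hu_sd: float = 0.0
    calc_hu_mean: float = 900.0
    calc_hu_sd: float = 0.0
    background_hu: float = -50.0
    noise_sd: float = 0.0  # additional global Gaussian noise
    seed: int = 0


def default_config(**overrides) -> PhantomConfig:
    """Full synthetic tree: aorta + 2 iliac + 2 mesenteric + 2 renal branches."""
    cfg = PhantomConfig(
        branch_specs=(
            BranchSpec(2, 12, "+x", 60.0),
            BranchSpec(2, 12, "-x", 60.0),
            BranchSpec(3, 44, "+y", 60.0),
            BranchSpec(3, 36, "-y", 60.0),
            BranchSpec(4, 56, "+x", 60.0),
            BranchSpec(4, 52, "-x", 60.0),
        ),
    )
    return replace(cfg, **overrides)


def tube_from_path(grid_shape, points, radius_mm: float,
                   spacing: float = 1.0) -> np.ndarray:
    """Rasterize a tube of given radius around a polyline of voxel coords."""
    mask = np.zeros(grid_shape, dtype=bool)
    pts = np.asarray(points, dtype=float)
    r_vox = radius_mm / spacing
    r_int = int(np.ceil(r_vox))
    # precompute sphere stamp offsets
    rng = np.arange(-r_int, r_int + 1)
    ox, oy, oz = np.meshgrid(rng, rng, rng, indexing="ij")
    inside = ox**2 + oy**2 + oz**2 <= r_vox**2
    offsets = np.stack([ox[inside], oy[inside], oz[inside]], axis=1)
    for p in pts:
        idx = np.rint(p).astype(int) + offsets
        ok = np.all((idx >= 0) & (idx < np.array(grid_shape)), axis=1)
        bad = idx[~ok]
        if bad.size:
            raise ValueError("tube leaves the grid; enlarge grid_shape")
        mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return mask


def _branch_path(cfg: PhantomConfig, spec: BranchSpec,
                 center: np.ndarray) -> np.ndarray:
    """Polyline from the aorta axis outward, sampled every 0.25 voxels."""
    step = 0.25
    d = _DIRECTIONS[spec.direction]
    zhat = np.array([0.0, 0.0, 1.0])
    total = cfg.aorta_radius_mm / cfg.spacing + spec.length_mm / cfg.spacing
    arc_len = spec.length_mm / cfg.spacing  # bending applies past the surface
    p = np.array([center[0], center[1], float(spec.attach_z)])
    pts = [p.copy()]
    s = 0.0
    while s < total:
        past = max(0.0, s - cfg.aorta_radius_mm / cfg.spacing)
        phi = np.deg2rad(spec.bend_deg) * (past / arc_len) if arc_len else 0.0
        tangent = np.cos(phi) * d + np.sin(phi) * zhat
        p = p + tangent * step
        pts.append(p.copy())
        s += step
    return np.asarray(pts)


def _ball_mask(grid_shape, center, radius_vox) -> np.ndarray:
    cx, cy, cz = center
    x, y, z = np.ogrid[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
    return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= radius_vox**2


def make_phantom(cfg: PhantomConfig) -> Tuple[HUVolume, ArteryLabelMap, CalcMask]:
    """Build the (HU, arteries, calcification) triple from a config."""
    shape = tuple(cfg.grid_shape)
    spacing = Spacing3D.make(cfg.spacing)
    center = np.array(
        cfg.aorta_center
        if cfg.aorta_center is not None
        else ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    )
    z0, z1 = cfg.aorta_z_range if cfg.aorta_z_range is not None else (0, shape[2] - 1)
    if not (0 <= z0 <= z1 < shape[2]):
        raise ValueError("aorta_z_range outside the grid")

    labels = np.zeros(shape, dtype=np.uint8)
    x, y = np.ogrid[: shape[0], : shape[1]]
    r_vox = cfg.aorta_radius_mm / cfg.spacing
    disc = (x - center[0]) ** 2 + (y - center[1]) ** 2 <= r_vox**2
    aorta = np.zeros(shape, dtype=bool)
    aorta[:, :, z0 : z1 + 1] = disc[:, :, None]
    labels[aorta] = 1

    for spec in cfg.branch_specs:
        if not (z0 <= spec.attach_z <= z1):
            raise ValueError(f"branch attaches at z={spec.attach_z} outside the aorta")
        path = _branch_path(cfg, spec, center)
        tube = tube_from_path(shape, path, cfg.branch_radius_mm, cfg.spacing)
        labels[tube & (labels == 0)] = spec.label

    calc = np.zeros(shape, dtype=bool)
    for les in cfg.lesions:
        cvox = np.rint(np.asarray(les.center)).astype(int)
        if np.any(cvox < 0) or np.any(cvox >= np.array(shape)):
            raise ValueError(f"lesion centre {les.center} outside the grid")
        if labels[tuple(cvox)] != les.host_label:
            raise ValueError(
                f"lesion centre {les.center} is not inside host label "
                f"{les.host_label} (found {labels[tuple(cvox)]})"
            )
        ball = _ball_mask(shape, les.center, les.radius_mm / cfg.spacing)
        calc |= ball & (labels == les.host_label)  # lesions clipped to host vessel

    rng = np.random.default_rng(cfg.seed)
    hu = np.full(shape, cfg.background_hu, dtype=np.float32)
    lumen = (labels != 0) & ~calc
    hu[lumen] = cfg.lumen_hu_mean
    hu[calc] = cfg.calc_hu_mean
    if cfg.lumen_hu_sd > 0:
        hu[lumen] += rng.normal(0, cfg.lumen_hu_sd, int(lumen.sum()))
    if cfg.calc_hu_sd > 0:
        hu[calc] += rng.normal(0, cfg.calc_hu_sd, int(calc.sum()))
    if cfg.noise_sd > 0:
        hu += rng.normal(0, cfg.noise_sd, shape).astype(np.float32)

    return (
        HUVolume(grid=hu, spacing=spacing),
        ArteryLabelMap(grid=labels, spacing=spacing),
        CalcMask(grid=calc.astype(np.uint8), spacing=spacing),
    )


def make_high_hu_case(cfg: Optional[PhantomConfig] = None,
                      lumen_hu: float = 550.0):
    """Phantom whose contrast-filled lumen exceeds the fixed 470 HU
    threshold, reproducing the clinical-method failure mode."""
    if cfg is None:
        cfg = default_config()
    if lumen_hu <= 470:
        raise ValueError("high-HU case requires lumen mean above 470 HU")
    return make_phantom(replace(cfg, lumen_hu_mean=lumen_hu))


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class CohortVariability:
    """Dispersion of per-case geometry and lesion load."""

    n_lesions_range: Tuple[int, int] = (1, 6)
    lesion_radius_range: Tuple[float, float] = (1.2, 3.2)
    branch_length_range: Tuple[float, float] = (15.0, 22.0)
    aorta_radius_range: Tuple[float, float] = (7.0, 9.0)


def _cohort_base_config() -> PhantomConfig:
    # Geometry chosen so that shortening is a geometric no-op: branches
    # shorter than the trim target and aorta top within the margin.
    return PhantomConfig(
        grid_shape=(72, 72, 64),
        branch_specs=(
            BranchSpec(2, 10, "+x", 20.0),
            BranchSpec(2, 10, "-x", 20.0),
            BranchSpec(3, 44, "+y", 20.0),
            BranchSpec(3, 36, "-y", 20.0),
            BranchSpec(4, 30, "+x", 20.0),
            BranchSpec(4, 26, "-x", 20.0),
        ),
        aorta_z_range=(0, 56),
    )


def _place_lesions(labels: np.ndarray, var: CohortVariability, n: int,
                   rng: np.random.Generator) -> List[LesionSpec]:
    """Rejection-sample non-touching lesions well inside their vessels."""
    shape = np.array(labels.shape)
    placed: List[LesionSpec] = []
    hosts = [1, 2, 3, 4]
    attempts = 0
    while len(placed) < n and attempts < 400:
        attempts += 1
        host = int(rng.choice(hosts))
        radius = float(rng.uniform(*var.lesion_radius_range))
        host_mask = labels == host
        if not host_mask.any():
            continue
        coords = np.argwhere(host_mask)
        c = coords[rng.integers(len(coords))].astype(float)
        if np.any(c < radius + 1) or np.any(c > shape - radius - 2):
            continue
        # keep lesions apart so each stays its own cluster
        ok = all(
            np.linalg.norm(c - np.asarray(p.center))
            > radius + p.radius_mm + 2.5
            for p in placed
        )
        if ok:
            placed.append(LesionSpec(tuple(c), radius, host))
    return placed


def make_cohort(
    n: int,
    base_cfg: Optional[PhantomConfig] = None,
    variability: Optional[CohortVariability] = None,
    seed: int = 0,
    noise_sd: float = 0.0,
):
    """Generate ``n`` randomized phantoms plus a construction truth table.

    The truth table holds per-case, per-group burden, cluster count and
    mean cluster size computed directly from the rasterized construction
    (lesion-by-lesion voxel counting), independent of the scoring
    pipeline.  Returns (list of (hu, arteries, calc), DataFrame).
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    base = base_cfg if base_cfg is not None else _cohort_base_config()
    var = variability if variability is not None else CohortVariability()
    phantoms = []
    rows = []
    for case in range(n):
        rng = np.random.default_rng(seed + 1000 * (case + 1))
        aorta_r = float(rng.uniform(*var.aorta_radius_range))
        branches = tuple(
            replace(b, length_mm=float(rng.uniform(*var.branch_length_range)))
            for b in base.branch_specs
        )
        cfg = replace(base, aorta_radius_mm=aorta_r, branch_specs=branches,
                      noise_sd=noise_sd, seed=seed + 1000 * (case + 1) + 7)
        # two-pass: rasterize vessels once to place lesions inside them
        _, labels_only, _ = make_phantom(replace(cfg, lesions=()))
        n_les = int(rng.integers(var.n_lesions_range[0],
                                 var.n_lesions_range[1] + 1))
        lesions = _place_lesions(labels_only.grid, var, n_les, rng)
        cfg = replace(cfg, lesions=tuple(lesions))
        hu, labels, calc = make_phantom(cfg)
        phantoms.append((hu, labels, calc))

        voxvol = Spacing3D.make(cfg.spacing).voxel_volume_mm3
        per_group_vols: Dict[str, List[float]] = {g: [] for g in GROUP_NAMES}
        for les in lesions:
            ball = _ball_mask(labels.grid.shape, les.center,
                              les.radius_mm / cfg.spacing)
            clipped = int(np.count_nonzero(ball & (labels.grid == les.host_label)))
            per_group_vols[ARTERY_LABELS[les.host_label]].append(clipped * voxvol)
        tot_calc = tot_artery = 0.0
        for lab, name in ARTERY_LABELS.items():
            artery_vol = float(np.count_nonzero(labels.grid == lab)) * voxvol
            calc_vol = float(sum(per_group_vols[name]))
            count = len(per_group_vols[name])
            rows.append({
                "case": case, "group": name,
                "artery_volume_mm3": artery_vol,
                "calc_volume_mm3": calc_vol,
                "burden": calc_vol / artery_vol if artery_vol else np.nan,
                "cluster_count": count,
                "mean_cluster_size_mm3": calc_vol / count if count else np.nan,
            })
            tot_calc += calc_vol
            tot_artery += artery_vol
        n_all = sum(len(v) for v in per_group_vols.values())
        rows.append({
            "case": case, "group": "combined",
            "artery_volume_mm3": tot_artery, "calc_volume_mm3": tot_calc,
            "burden": tot_calc / tot_artery if tot_artery else np.nan,
            "cluster_count": n_all,
            "mean_cluster_size_mm3": tot_calc / n_all if n_all else np.nan,
        })
    truth = pd.DataFrame(rows)
    return phantoms, truth
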