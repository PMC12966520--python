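"""NIfTI volume I/O, domain types, and isotropic resampling.

Volumes are represented as plain numpy grids plus voxel spacing and an
affine.  The array axis convention is (x, y, z) with axis 2 the
superior-inferior axis, increasing index = superior; this is asserted
from the NIfTI affine on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Union

import nibabel as nib
import numpy as np
from scipy import ndimage


ARTERY_LABELS = {1: "aorta", 2: "iliac", 3: "mesenteric", 4: "renal"}
GROUP_NAMES = ("aorta", "iliac", "mesenteric", "renal")


class Spacing3D(NamedTuple):
    """Voxel edge lengths in millimetres."""

    sx: float
    sy: float
    sz: float

    @classmethod
    def make(cls, spacing: Union[float, "Spacing3D", tuple]) -> "Spacing3D":
        if np.isscalar(spacing):
            spacing = (float(spacing),) * 3
        s = cls(*(float(v) for v in spacing))
        if not all(v > 0 for v in s):
            raise ValueError(f"spacing must be strictly positive, got {s}")
        return s

    @property
    def voxel_volume_mm3(self) -> float:
        return self.sx * self.sy * self.sz

    def is_isotropic(self, target: float = None, tol: float = 1e-6) -> bool:
        ref = self.sx if target is None else target
        return all(abs(v - ref) <= tol for v in self)


def _default_affine(spacing: Spacing3D) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class BaseVolume:
    """Shared container: 3D grid + spacing + affine."""

    grid: np.ndarray
    spacing: Spacing3D
    affine: np.ndarray = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.grid.shape}")
        self.spacing = Spacing3D.make(self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)
        self._validate()

    def _validate(self):  # pragma: no cover - overridden
        pass

    @property
    def shape(self):
        return self.grid.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing.voxel_volume_mm3


@dataclass
class HUVolume(BaseVolume):
    """CTA intensity volume in Hounsfield units."""

    def _validate(self):
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("HU volume contains non-finite values")
        self.grid = self.grid.astype(np.float32, copy=False)


@dataclass
class ArteryLabelMap(BaseVolume):
    """Integer label map: 0 background, 1 aorta, 2 iliac, 3 mesenteric, 4 renal."""

    def _validate(self):
        if not np.issubdtype(self.grid.dtype, np.integer):
            rounded = np.rint(self.grid)
            if not np.allclose(self.grid, rounded, atol=1e-3):
                raise ValueError("artery label map holds non-integer values")
            self.grid = rounded.astype(np.uint8)
        bad = np.setdiff1d(np.unique(self.grid), [0, 1, 2, 3, 4])
        if bad.size:
            raise ValueError(
                f"artery label map contains values outside {{0..4}}: {bad.tolist()}"
            )
        self.grid = self.grid.astype(np.uint8, copy=False)

    def mask(self, label: int) -> np.ndarray:
        return self.grid == label


@dataclass
class CalcMask(BaseVolume):
    """Binary calcification mask."""

    def _validate(self):
        vals = np.unique(self.grid)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError(f"calcification mask must be binary, found {vals.tolist()}")
        self.grid = self.grid.astype(np.uint8, copy=False)


AnyVolume = Union[HUVolume, ArteryLabelMap, CalcMask]

_KINDS = {"hu": HUVolume, "arteries": ArteryLabelMap, "calc": CalcMask}


def _spacing_from_img(img) -> Spacing3D:
    return Spacing3D.make(tuple(float(z) for z in img.header.get_zooms()[:3]))


def _assert_superior_axis(affine: np.ndarray):
    # Axis 2 must map dominantly onto +S in world space (RAS convention).
    col = affine[:3, 2]
    if abs(col[2]) < max(abs(col[0]), abs(col[1])) or col[2] <= 0:
        raise ValueError(
            "array axis 2 is not the superior axis with increasing index = "
            f"superior (affine column {col.tolist()}); reorient the input first"
        )


def read_volume(path, kind: str = "auto") -> AnyVolume:
    """Read a NIfTI file into the appropriate domain type.

    Parameters
    ----------
    path : path-like
        ``.nii`` or ``.nii.gz`` file.
    kind : {"auto", "hu", "arteries", "calc"}
        Force the returned type, or infer it: float data -> HUVolume,
        integer data within {0,1} -> CalcMask, within {0..4} -> ArteryLabelMap.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad content
        raise ValueError(f"{path} is not a readable NIfTI file: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    spacing = _spacing_from_img(img)
    affine = img.affine
    _assert_superior_axis(affine)
    if kind != "auto":
        return _KINDS[kind](grid=data, spacing=spacing, affine=affine)
    if np.issubdtype(data.dtype, np.floating) and not np.allclose(
        data, np.rint(data), atol=1e-6
    ):
        return HUVolume(grid=data, spacing=spacing, affine=affine)
    ints = np.rint(data).astype(np.int64)
    uniq = np.unique(ints)
    if np.all(np.isin(uniq, [0, 1, 2, 3, 4])):
        return ArteryLabelMap(grid=ints, spacing=spacing, affine=affine)
    return HUVolume(grid=data.astype(np.float32), spacing=spacing, affine=affine)


def write_volume(vol: AnyVolume, path) -> Path:
    """Write a volume as NIfTI; dtype follows the domain type."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(vol, HUVolume):
        data = vol.grid.astype(np.float32)
    else:
        data = vol.grid.astype(np.uint8)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_zooms(tuple(vol.spacing))
    nib.save(img, str(path))
    return path


def resample_isotropic(vol: AnyVolume, target=1.0) -> AnyVolume:
    """Resample a volume onto an isotropic grid.

    Label maps and masks use nearest-neighbour interpolation (no new
    labels); HU volumes use trilinear.  The output grid shares the input
    origin; output shape = ceil(physical extent / target spacing).
    """
    target = Spacing3D.make(target)
    if any(n == 0 for n in vol.grid.shape):
        raise ValueError("cannot resample a degenerate (zero-size) grid")
    if vol.spacing.is_isotropic() and all(
        abs(a - b) <= 1e-9 for a, b in zip(vol.spacing, target)
    ):
        return vol
    src = vol.spacing
    new_shape = tuple(
        int(np.ceil(n * s / t)) for n, s, t in zip(vol.grid.shape, src, target)
    )
    # Sample the input at the physical positions of the new voxel centres.
    axes = [
        np.arange(n, dtype=np.float64) * t / s
        for n, s, t in zip(new_shape, src, target)
    ]
    coords = np.meshgrid(*axes, indexing="ij", sparse=True)
    order = 1 if isinstance(vol, HUVolume) else 0
    out = ndimage.map_coordinates(
        vol.grid.astype(np.float32), np.broadcast_arrays(*coords), order=order,
        mode="nearest",
    )
    new_affine = vol.affine.copy()
    scale = np.array([t / s for s, t in zip(src, target)])
    new_affine[:3, :3] = vol.affine[:3, :3] * scale[np.newaxis, :]
    cls = type(vol)
    return cls(grid=out, spacing=target, affine=new_affine)
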