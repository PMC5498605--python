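"""Binary label-map volumes: the segmentation representation all geometry derives from.

A :class:`LabelMapVolume` is a 3D integer grid with physical voxel spacing and
origin, mirroring how aneurysm and lumen segmentations arrive from clinical
imaging (NRRD / MetaImage).  Axis order is (x, y, z) with ``voxels[i, j, k]``
at world position ``origin + spacing * (i, j, k)`` (voxel-center convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import SpecError

__all__ = [
    "LabelMapVolume",
    "read_labelmap",
    "write_labelmap",
    "dice",
    "subtract_lumen",
]


@dataclass
class LabelMapVolume:
    """Binary voxel volume with physical spacing and origin (mm)."""

    voxels: np.ndarray  # 3D integer array, axis order (x, y, z)
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise SpecError("label map must be a 3D array")
        if not np.isin(np.unique(self.voxels), [0, 1]).all():
            raise SpecError("label map values must be 0 or 1")
        if any(s <= 0 for s in self.spacing):
            raise SpecError("voxel spacing must be strictly positive")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def count(self) -> int:
        return int(np.count_nonzero(self.voxels))

    def require_nonempty(self) -> None:
        if self.count == 0:
            raise SpecError("label map has no foreground voxels")

    def same_grid(self, other: "LabelMapVolume") -> bool:
        return (
            self.voxels.shape == other.voxels.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def voxel_centers(self) -> np.ndarray:
        """World coordinates (mm) of all foreground voxel centers, shape (n, 3)."""
        idx = np.argwhere(self.voxels > 0).astype(float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def centroid(self) -> np.ndarray:
        """World centroid (mm) of the foreground."""
        self.require_nonempty()
        return self.voxel_centers().mean(axis=0)

    def volume(self) -> float:
        """Foreground volume in mm^3 (voxel-count estimate)."""
        return self.count * float(np.prod(self.spacing))


def _to_sitk(lm: LabelMapVolume) -> sitk.Image:
    # SimpleITK uses (z, y, x) array order; our convention is (x, y, z).
    img = sitk.GetImageFromArray(np.ascontiguousarray(lm.voxels.T).astype(np.uint8))
    img.SetSpacing(tuple(lm.spacing))
    img.SetOrigin(tuple(lm.origin))
    return img


def _from_sitk(img: sitk.Image) -> LabelMapVolume:
    arr = sitk.GetArrayFromImage(img).T  # back to (x, y, z)
    return LabelMapVolume(
        voxels=(arr > 0).astype(np.uint8),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )


def read_labelmap(path: str | Path) -> LabelMapVolume:
    """Read a binary label map from NRRD or MetaImage (.mha/.mhd)."""
    img = sitk.ReadImage(str(path))
    lm = _from_sitk(img)
    lm.require_nonempty()
    return lm


def write_labelmap(lm: LabelMapVolume, path: str | Path) -> None:
    """Write a label map as NRRD or MetaImage, chosen by file extension."""
    sitk.WriteImage(_to_sitk(lm), str(path), useCompression=False)


def dice(a: LabelMapVolume, b: LabelMapVolume) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) on a shared grid."""
    if a.voxels.shape != b.voxels.shape:
        raise SpecError("dice requires label maps on the same grid")
    inter = np.count_nonzero((a.voxels > 0) & (b.voxels > 0))
    denom = a.count + b.count
    return 2.0 * inter / denom if denom else 1.0


def subtract_lumen(aaa: LabelMapVolume, lumen: LabelMapVolume) -> LabelMapVolume:
    """AAA minus lumen, after clipping the lumen into the AAA label.

    The lumen segmentation is first intersected with the AAA label (containment
    enforcement: voxels of the lumen protruding outside the aneurysm are
    discarded), then subtracted voxel-wise.  The result is the wall + thrombus
    shell solid.
    """
    if not aaa.same_grid(lumen):
        raise SpecError("AAA and lumen label maps must share the same grid")
    clipped = (lumen.voxels > 0) & (aaa.voxels > 0)
    out = (aaa.voxels > 0) & ~clipped
    if not out.any():
        raise SpecError("subtraction produced an empty label (lumen covers AAA)")
    return LabelMapVolume(out.astype(np.uint8), aaa.spacing, aaa.origin)
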