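"""Rigid label-map registration (e.g. aligning an MRI segmentation to CT).

Only rigid alignment is provided: label maps carry no intensity information
that could drive a deformable match, and the downstream analysis needs the
two segmentations in one frame, not a warped geometry.  The transform is
initialized from foreground centroids and principal axes (second moments),
disambiguated by label overlap (Dice), and refined with point-to-surface ICP
between the marching-cubes surfaces of the two labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .errors import SpecError
from .labelmap import LabelMapVolume, dice
from .surface import extract_surface

__all__ = ["RigidTransform", "register_rigid", "resample_labelmap"]


@dataclass
class RigidTransform:
    """x_fixed = rotation @ x_moving + translation (world mm coordinates)."""

    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,)
    centroid_only: bool = False  # principal axes were degenerate

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise SpecError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise SpecError("rotation must be proper (det = +1)")

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation, self.centroid_only)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _moments(lm: LabelMapVolume):
    pts = lm.voxel_centers()
    c = pts.mean(axis=0)
    d = pts - c
    cov = d.T @ d / len(d)
    w, v = np.linalg.eigh(cov)  # ascending
    w, v = w[::-1], v[:, ::-1]  # principal first
    if np.linalg.det(v) < 0:  # make it a proper rotation
        v = v.copy()
        v[:, -1] *= -1
    return c, w, v


def _surface_points(lm: LabelMapVolume, n: int = 800) -> np.ndarray:
    s = extract_surface(lm)
    v = s.vertices
    if len(v) > n:
        step = len(v) // n
        v = v[::step]
    return v


def _icp(moving_pts: np.ndarray, fixed_pts: np.ndarray, R0, t0, iters: int = 30):
    """Point-to-point ICP refinement starting from (R0, t0)."""
    tree = cKDTree(fixed_pts)
    R, t = R0.copy(), t0.copy()
    prev = np.inf
    for _ in range(iters):
        mp = moving_pts @ R.T + t
        d, idx = tree.query(mp)
        # trim worst 10% correspondences for robustness
        keep = d <= np.percentile(d, 90)
        src, dst = moving_pts[keep], fixed_pts[idx[keep]]
        err = float(np.mean(d[keep] ** 2))
        if prev - err < 1e-10:
            break
        prev = err
        sc, dc = src.mean(axis=0), dst.mean(axis=0)
        H = (src - sc).T @ (dst - dc)
        U, _, Vt = np.linalg.svd(H)
        D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
        R = Vt.T @ D @ U.T
        t = dc - R @ sc
    return R, t


def register_rigid(fixed: LabelMapVolume, moving: LabelMapVolume) -> RigidTransform:
    """Rigid transform mapping ``moving`` world coordinates into ``fixed``'s frame.

    Initialization: centroid + principal-axes alignment; the four proper
    sign combinations of the axes are scored by Dice after resampling and the
    best is kept.  Refinement: trimmed point-to-point ICP on surface points.
    The refined transform is accepted only if it does not decrease Dice.
    Degenerate moments (spherically symmetric label) fall back to
    centroid-only initialization, flagged on the returned transform.
    """
    fixed.require_nonempty()
    moving.require_nonempty()
    cf, wf, vf = _moments(fixed)
    cm, wm, vm = _moments(moving)

    degenerate = bool(np.min(np.abs(np.diff(wf)) / max(wf[0], 1e-12)) < 1e-3
                      or np.min(np.abs(np.diff(wm)) / max(wm[0], 1e-12)) < 1e-3)
    candidates: list[RigidTransform] = []
    if degenerate:
        candidates.append(RigidTransform(np.eye(3), cf - cm, centroid_only=True))
    else:
        for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
            S = np.diag([sx, sy, sx * sy])  # keeps det = +1
            R = vf @ S @ vm.T
            if np.linalg.det(R) < 0:  # pragma: no cover - S preserves det
                continue
            candidates.append(RigidTransform(R, cf - R @ cm))

    def score(t: RigidTransform) -> float:
        return dice(fixed, resample_labelmap(moving, t, fixed))

    best = max(candidates, key=score)
    best_dice = score(best)

    # ICP refinement on surface point clouds
    fp = _surface_points(fixed)
    mp = _surface_points(moving)
    R, t = _icp(mp, fp, best.rotation, best.translation)
    refined = RigidTransform(R, t, centroid_only=best.centroid_only)
    if score(refined) >= best_dice:
        return refined
    return best


def resample_labelmap(
    moving: LabelMapVolume, t: RigidTransform, reference: LabelMapVolume
) -> LabelMapVolume:
    """Nearest-neighbour resample of ``moving`` onto the reference grid after
    applying ``t`` (moving -> fixed/reference frame)."""
    inv = t.inverse()
    shape = reference.voxels.shape
    ax = [np.arange(n, dtype=float) for n in shape]
    I, J, K = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([I.ravel(), J.ravel(), K.ravel()], axis=1)
    world = pts * np.asarray(reference.spacing) + np.asarray(reference.origin)
    src = inv.apply(world)
    src_idx = (src - np.asarray(moving.origin)) / np.asarray(moving.spacing)
    vals = ndi.map_coordinates(
        moving.voxels.astype(np.float32),
        src_idx.T,
        order=0,
        mode="constant",
        cval=0.0,
    )
    out = (vals.reshape(shape) > 0.5).astype(np.uint8)
    return LabelMapVolume(out, reference.spacing, reference.origin)
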