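"""Synthetic fusiform AAA phantoms with closed-form ground truth.

Patient segmentations cannot ship with the package, so every downstream stage
is exercised on parametric phantoms: a tube with a Gaussian-bump dilation
(the aneurysm sac) and an eccentric cylindrical lumen, voxelized at a
configurable anisotropic spacing.  Because the outer radius profile and lumen
placement are analytic, maximum diameter, neck diameter, normalized diameter
(NORD) and maximum intraluminal thrombus (ILT) thickness are known exactly.

The outer radius profile is

    r(z) = r_neck + (r_max - r_neck) * exp(-((z - z_c) / w)^2)

and the lumen is a straight tube of constant radius whose axis is displaced
laterally (along +x) by ``ecc * exp(-((z - z_c)/w)^2)``, so the thrombus layer
is thickest on the far side of the bulge, as in typical fusiform aneurysms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SpecError
from .labelmap import LabelMapVolume

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic fusiform AAA.

    All lengths in mm.  ``lumen_eccentricity`` is the lateral offset of the
    lumen axis at the bulge center; 0 gives a concentric lumen.
    ``wall_thickness`` is the (uniform) wall the analysis will carve from the
    outer surface; it only enters the analytic ILT-thickness ground truth.
    """

    neck_radius: float = 11.0
    max_radius: float = 24.0
    bulge_center_z: float = 60.0
    bulge_halfwidth: float = 20.0
    total_length: float = 120.0
    lumen_radius: float = 9.0
    lumen_eccentricity: float = 0.0
    wall_thickness: float = 1.5
    voxel_spacing: tuple[float, float, float] = (0.625, 0.625, 2.0)
    noise_amplitude: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lumen_radius < self.neck_radius <= self.max_radius):
            raise SpecError("need lumen_radius < neck_radius <= max_radius")
        if self.total_length <= 4 * self.bulge_halfwidth:
            raise SpecError("need total_length > 4 * bulge_halfwidth")
        if any(s <= 0 for s in self.voxel_spacing):
            raise SpecError("voxel spacing must be positive")
        # Lumen must stay inside the *inner wall* everywhere along the axis.
        z = np.linspace(0.0, self.total_length, 512)
        gap = (
            self.outer_radius(z)
            - self.wall_thickness
            - self.lumen_offset(z)
            - self.lumen_radius
        )
        if gap.min() <= 0:
            raise SpecError("lumen not containable inside the wall for this spec")

    # -- analytic profile ---------------------------------------------------
    def _bump(self, z: np.ndarray | float) -> np.ndarray | float:
        return np.exp(-(((np.asarray(z) - self.bulge_center_z) / self.bulge_halfwidth) ** 2))

    def outer_radius(self, z: np.ndarray | float):
        """Outer wall radius r(z) of the fusiform profile."""
        return self.neck_radius + (self.max_radius - self.neck_radius) * self._bump(z)

    def lumen_offset(self, z: np.ndarray | float):
        """Lateral (+x) displacement of the lumen axis at height z."""
        return self.lumen_eccentricity * self._bump(z)


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic ground truth for a phantom (all lengths mm)."""

    max_diameter: float
    neck_diameter: float
    nord_max: float
    max_ilt_thickness: float
    radius_profile: dict  # z (mm) -> outer radius (mm)

    def __post_init__(self) -> None:
        assert abs(self.nord_max - self.max_diameter / self.neck_diameter) < 1e-9
        assert self.max_ilt_thickness >= 0


def _voxelize(spec: PhantomSpec, inside) -> LabelMapVolume:
    sx, sy, sz = spec.voxel_spacing
    # grid extent: lateral half-size covering max radius with margin
    half = spec.max_radius + max(abs(spec.lumen_eccentricity), 0.0) + 3.0
    nx = int(np.ceil(2 * half / sx)) + 1
    ny = int(np.ceil(2 * half / sy)) + 1
    nz = int(np.round(spec.total_length / sz)) + 1
    x = -half + sx * np.arange(nx)
    y = -half + sy * np.arange(ny)
    z = sz * np.arange(nz)
    X = x[:, None, None]
    Y = y[None, :, None]
    Z = z[None, None, :]
    vox = inside(X, Y, Z).astype(np.uint8)
    return LabelMapVolume(vox, spec.voxel_spacing, (-half, -half, 0.0))


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[LabelMapVolume, LabelMapVolume, PhantomTruth]:
    """Voxelize a phantom; returns (aaa, lumen) label maps and analytic truth.

    Voxel-center sampling: a voxel belongs to a label iff its center lies
    inside the analytic solid.  Both labels share one grid and the lumen label
    is a strict subset of the AAA label.  Optional radial surface noise
    (``noise_amplitude`` > 0) perturbs the outer boundary deterministically
    from ``rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    # Smooth pseudo-random radial perturbation: low-order Fourier series in
    # (theta, z) so the surface stays well-resolved at the voxel scale.
    if spec.noise_amplitude > 0:
        coef = rng.normal(size=(3, 3, 2)) * spec.noise_amplitude / 3.0

        def perturb(theta, zfrac):
            out = 0.0
            for m in range(3):
                for n in range(3):
                    out = out + coef[m, n, 0] * np.cos(m * theta + 2 * np.pi * n * zfrac)
                    out = out + coef[m, n, 1] * np.sin(m * theta + 2 * np.pi * n * zfrac)
            return out

    else:
        perturb = None

    def aaa_inside(X, Y, Z):
        r = np.sqrt(X**2 + Y**2)
        router = spec.outer_radius(Z)
        if perturb is not None:
            theta = np.arctan2(Y, X)
            router = router + perturb(theta, Z / spec.total_length)
        return r <= router

    def lumen_inside(X, Y, Z):
        off = spec.lumen_offset(Z)
        r = np.sqrt((X - off) ** 2 + Y**2)
        return r <= spec.lumen_radius

    aaa = _voxelize(spec, aaa_inside)
    lumen = _voxelize(spec, lumen_inside)
    # containment is analytic for valid specs; enforce voxel-wise regardless
    lumen = LabelMapVolume(
        (lumen.voxels & aaa.voxels).astype(np.uint8), lumen.spacing, lumen.origin
    )
    aaa.require_nonempty()
    lumen.require_nonempty()

    z = np.linspace(0.0, spec.total_length, 2049)
    r = np.asarray(spec.outer_radius(z))
    neck_d = 2.0 * spec.neck_radius
    max_d = 2.0 * float(r.max())
    # Max wall-to-lumen gap: inner wall radius + local lumen offset - lumen radius,
    # maximized over z (the far side of the bulge from the displaced lumen axis).
    gap = r - spec.wall_thickness + np.asarray(spec.lumen_offset(z)) - spec.lumen_radius
    truth = PhantomTruth(
        max_diameter=max_d,
        neck_diameter=neck_d,
        nord_max=max_d / neck_d,
        max_ilt_thickness=float(max(gap.max(), 0.0)),
        radius_profile={float(zz): float(rr) for zz, rr in zip(z[::128], r[::128])},
    )
    return aaa, lumen, truth
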