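"""Rupture potential index: diameters, wall strength, stress/strength ratio.

Wall strength is estimated from the statistical model of Vande Geest and
co-workers: strength (in N/cm²) decreases with the square root of the local
intraluminal thrombus thickness and with the normalized diameter (NORD,
local diameter over proximal neck diameter), is lower with a family history
of aneurysm, and higher in males:

    strength = 71.9 - 37.9 (sqrt(ILT_cm) - 0.81) - 15.6 (NORD - 2.46)
               - 21.3 HIST + 19.3 SEX        [N/cm²]

with HIST = +1/2 (family history) or -1/2, SEX = +1/2 (male) or -1/2, ILT
in cm.  The rupture potential index is the pointwise ratio of computed wall
stress to estimated strength; RPI = 1 is the theoretical rupture point.

Stress peaks near the constrained vessel ends are artifacts of the boundary
conditions; an exclusion band removes them before maxima are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SpecError
from .surface import TriSurface

__all__ = [
    "PatientFactors",
    "DiameterProfile",
    "StrengthModelParams",
    "diameter_profile",
    "nord_field",
    "wall_strength",
    "rpi_field",
    "boundary_exclusion",
    "voxel_radius_error_percent",
]

N_PER_CM2_TO_MPA = 0.01


@dataclass(frozen=True)
class PatientFactors:
    """Covariates of the strength model."""

    sex: str  # "male" | "female"
    family_history: bool

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise SpecError("sex must be 'male' or 'female'")

    @property
    def hist_coded(self) -> float:
        return 0.5 if self.family_history else -0.5

    @property
    def sex_coded(self) -> float:
        return 0.5 if self.sex == "male" else -0.5


@dataclass(frozen=True)
class StrengthModelParams:
    """Constants of the statistical wall-strength model (N/cm² scale).

    Shipped defaults follow the published population model; they are
    configuration, not code, and are echoed in every run log.
    ``strength_floor`` (MPa) guards against nonphysical negative strengths
    when the model is evaluated outside its fitted covariate range.
    """

    intercept: float = 71.9
    ilt_coefficient: float = 37.9  # per sqrt(cm)
    ilt_offset: float = 0.81  # sqrt(cm)
    nord_coefficient: float = 15.6
    nord_offset: float = 2.46
    history_coefficient: float = 21.3
    sex_coefficient: float = 19.3
    strength_floor: float = 0.10  # MPa

    def __post_init__(self) -> None:
        if self.strength_floor <= 0:
            raise SpecError("strength_floor must be positive")


@dataclass
class DiameterProfile:
    """Equivalent diameter vs axial station, plus the derived scalars."""

    stations: np.ndarray  # z (mm), ascending
    diameters: np.ndarray  # d(z) (mm)
    max_diameter: float
    neck_diameter: float

    @property
    def nord_max(self) -> float:
        return self.max_diameter / self.neck_diameter


def diameter_profile(
    external: TriSurface, station_spacing: float = 1.0, neck_fraction: float = 0.10
) -> DiameterProfile:
    """Cross-sectional diameter profile of the external wall surface.

    At each axial station the surface is sliced and the equivalent-area
    diameter 2*sqrt(A/pi) recorded; the neck diameter is the mean over the
    proximal ``neck_fraction`` of stations (the non-dilated segment distal to
    the renal arteries, by construction the low-z end).
    """
    m = external.as_trimesh()
    z0, z1 = external.vertices[:, 2].min(), external.vertices[:, 2].max()
    # stay clear of the open ends by half a station
    zs = np.arange(z0 + 0.5 * station_spacing, z1 - 0.25 * station_spacing, station_spacing)
    if len(zs) < 5:
        raise SpecError("surface spans fewer than 5 axial stations")
    areas = np.empty(len(zs))
    for i, z in enumerate(zs):
        area = _section_area(m, external, z)
        areas[i] = area
    d = 2.0 * np.sqrt(areas / np.pi)
    n_neck = max(1, int(np.ceil(neck_fraction * len(zs))))
    neck = float(d[:n_neck].mean())
    return DiameterProfile(
        stations=zs, diameters=d, max_diameter=float(d.max()), neck_diameter=neck
    )


def _section_area(m, external: TriSurface, z: float) -> float:
    try:
        sec = m.section(plane_origin=[0, 0, z], plane_normal=[0, 0, 1])
        if sec is not None:
            planar, _ = sec.to_2D()
            a = float(planar.area)
            if a > 0:
                return a
    except Exception:
        pass
    # fallback: convex hull of the slice's intersection points
    import trimesh

    segs = trimesh.intersections.mesh_plane(m, [0, 0, 1], [0, 0, z])
    if len(segs) == 0:
        raise SpecError(f"no cross-section at z={z}")
    pts = segs.reshape(-1, 3)[:, :2]
    from scipy.spatial import ConvexHull

    return float(ConvexHull(pts).volume)  # 2D hull "volume" is its area


def nord_field(external: TriSurface, dp: DiameterProfile) -> np.ndarray:
    """Per-vertex local diameter over neck diameter, by nearest station."""
    z = external.vertices[:, 2]
    idx = np.clip(
        np.searchsorted(dp.stations, z), 0, len(dp.stations) - 1
    )
    left = np.clip(idx - 1, 0, len(dp.stations) - 1)
    pick = np.where(
        np.abs(dp.stations[left] - z) <= np.abs(dp.stations[idx] - z), left, idx
    )
    return dp.diameters[pick] / dp.neck_diameter


def wall_strength(
    ilt_thickness_mm: np.ndarray,
    nord: np.ndarray,
    pf: PatientFactors,
    params: StrengthModelParams = StrengthModelParams(),
) -> np.ndarray:
    """Per-vertex wall strength in MPa (floored at ``strength_floor``)."""
    ilt = np.asarray(ilt_thickness_mm, dtype=float)
    nord = np.asarray(nord, dtype=float)
    if (ilt < 0).any():
        raise SpecError("negative ILT thickness")
    ilt_cm = ilt / 10.0
    s_ncm2 = (
        params.intercept
        - params.ilt_coefficient * (np.sqrt(ilt_cm) - params.ilt_offset)
        - params.nord_coefficient * (nord - params.nord_offset)
        - params.history_coefficient * pf.hist_coded
        + params.sex_coefficient * pf.sex_coded
    )
    s_mpa = s_ncm2 * N_PER_CM2_TO_MPA
    return np.maximum(s_mpa, params.strength_floor)


def rpi_field(
    sigma1: np.ndarray, strength: np.ndarray, exclusion_mask: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """RPI = stress / strength per vertex, and its maximum outside the mask.

    An RPI of one is the theoretical rupture point; values above one imply a
    high likelihood of rupture.
    """
    sigma1 = np.asarray(sigma1, dtype=float)
    strength = np.asarray(strength, dtype=float)
    if (strength <= 0).any():
        raise SpecError("strength must be positive everywhere")
    rpi = sigma1 / strength
    keep = np.ones(len(rpi), dtype=bool)
    if exclusion_mask is not None:
        keep &= ~np.asarray(exclusion_mask, dtype=bool)
        if not keep.any():
            raise SpecError("exclusion mask covers all vertices")
    return rpi, float(rpi[keep].max())


def boundary_exclusion(
    points: np.ndarray, distance: float = 10.0, axis: int = 2
) -> np.ndarray:
    """Mask of points within an axial distance of either constrained end.

    Stress concentrations at the fixed caps are artifacts; the default band
    is 10 mm from each end.  A band covering everything is rejected.
    """
    if distance < 0:
        raise SpecError("exclusion distance must be >= 0")
    z = np.asarray(points)[:, axis]
    lo, hi = z.min(), z.max()
    mask = (z < lo + distance) | (z > hi - distance)
    if mask.all() and len(mask) > 0 and distance > 0:
        raise SpecError("exclusion band covers the whole vessel")
    return mask


def voxel_radius_error_percent(voxel_size_mm: float, radius_mm: float) -> float:
    """Relative radius error (percent) from a one-voxel segmentation error.

    E.g. one 0.625 mm in-plane voxel on a 25 mm radius is a 2.5% error.
    """
    if radius_mm <= 0 or voxel_size_mm <= 0:
        raise SpecError("voxel size and radius must be positive")
    return 100.0 * voxel_size_mm / radius_mm
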