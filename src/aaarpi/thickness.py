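"""Sparse wall-thickness measurements -> smooth per-vertex thickness field.

Wall thickness can rarely be measured everywhere on an aneurysm; typically a
handful of point measurements exist (from registered MRI, ex-vivo samples or
CT estimation).  Each surface vertex first inherits the thickness of its
Euclidean-nearest measurement (a Voronoi-like piecewise-constant partition of
the surface), and the resulting field is then relaxed by iterated
neighbour-average (umbrella) smoothing over the surface graph.  A single
measurement file means constant-thickness mode.

Annotation format: CSV with the exact header ``x,y,z,thickness_mm`` and one
measurement per following row (positions in mm in the surface frame).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import SpecError
from .surface import TriSurface

__all__ = [
    "ThicknessMeasurement",
    "load_thickness_annotations",
    "assign_nearest",
    "smooth_field",
    "thickness_field",
]


@dataclass(frozen=True)
class ThicknessMeasurement:
    point: tuple[float, float, float]  # mm
    thickness: float  # mm

    def __post_init__(self) -> None:
        if not self.thickness > 0:
            raise SpecError(f"thickness must be positive, got {self.thickness}")


_HEADER = ["x", "y", "z", "thickness_mm"]


def load_thickness_annotations(paths: list[str | Path]) -> list[ThicknessMeasurement]:
    """Read measurement CSV files; one file total => constant-thickness mode.

    Measurement order follows the file order, then row order within a file
    (ties in the nearest-point assignment break toward the earlier index).
    """
    if not paths:
        raise SpecError("no thickness annotation files given")
    out: list[ThicknessMeasurement] = []
    for p in paths:
        p = Path(p)
        if not p.exists():
            raise SpecError(f"annotation file not found: {p}")
        with open(p, newline="") as fh:
            rows = list(csv.reader(fh))
        if not rows or [c.strip().lower() for c in rows[0]] != _HEADER:
            raise SpecError(f"{p}: expected header {','.join(_HEADER)}")
        for row in rows[1:]:
            if not row or all(not c.strip() for c in row):
                continue
            try:
                x, y, z, th = (float(c) for c in row[:4])
            except ValueError as e:
                raise SpecError(f"{p}: bad row {row!r}") from e
            if th <= 0:
                raise SpecError(f"{p}: nonpositive thickness {th}")
            out.append(ThicknessMeasurement((x, y, z), th))
    if not out:
        raise SpecError("annotation files contain no measurements")
    return out


def assign_nearest(
    surface: TriSurface, ms: list[ThicknessMeasurement]
) -> np.ndarray:
    """Each vertex takes the thickness of its Euclidean-nearest measurement.

    Exact ties break toward the lowest measurement index.
    """
    if not ms:
        raise SpecError("need at least one measurement")
    pts = np.asarray([m.point for m in ms], dtype=float)
    vals = np.asarray([m.thickness for m in ms], dtype=float)
    d = np.linalg.norm(surface.vertices[:, None, :] - pts[None, :, :], axis=2) \
        if len(ms) <= 64 else None
    if d is not None:
        idx = np.argmin(d, axis=1)  # argmin returns first minimum: lowest index
    else:
        _, idx = cKDTree(pts).query(surface.vertices)
    return vals[idx]


def _vertex_adjacency(surface: TriSurface):
    t = surface.triangles
    e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    return e


def smooth_field(
    surface: TriSurface, field: np.ndarray, iterations: int = 10
) -> np.ndarray:
    """Iterated umbrella smoothing of a per-vertex scalar over the surface graph.

    Each iteration replaces a vertex value by the mean of its 1-ring
    neighbours.  Convex averaging implies a discrete maximum principle: the
    smoothed field stays within the input [min, max].
    """
    if iterations < 0:
        raise SpecError("iterations must be >= 0")
    f = np.asarray(field, dtype=float).copy()
    if len(f) != surface.n_vertices:
        raise SpecError("field length != vertex count")
    if iterations == 0:
        return f
    e = _vertex_adjacency(surface)
    n = surface.n_vertices
    deg = np.zeros(n)
    np.add.at(deg, e[:, 0], 1.0)
    np.add.at(deg, e[:, 1], 1.0)
    deg[deg == 0] = 1.0
    for _ in range(iterations):
        acc = np.zeros(n)
        np.add.at(acc, e[:, 0], f[e[:, 1]])
        np.add.at(acc, e[:, 1], f[e[:, 0]])
        f = acc / deg
    return f


def thickness_field(
    surface: TriSurface,
    ms: list[ThicknessMeasurement],
    smoothing_iterations: int = 10,
) -> np.ndarray:
    """Nearest assignment followed by smoothing; constant if one measurement."""
    f = assign_nearest(surface, ms)
    if len(ms) == 1:
        return f
    return smooth_field(surface, f, smoothing_iterations)
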