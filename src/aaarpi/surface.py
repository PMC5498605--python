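"""Triangulated surfaces: extraction from label maps, smoothing, measures.

Surfaces live in world (mm) coordinates.  Closed surfaces are oriented
outward from the solid they enclose.  Surfaces extracted from label maps that
touch the first/last axial slice are open tubes (the vessel is cut at the
segmentation extent); end caps are added later, at the meshing stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from skimage import measure as _skmeasure

from .errors import GeometryError
from .labelmap import LabelMapVolume

__all__ = [
    "TriSurface",
    "extract_surface",
    "smooth_surface",
    "boundary_loops",
    "enclosed_volume",
    "is_closed",
    "vertex_normals",
    "NearestPointLocator",
]


@dataclass
class TriSurface:
    """Indexed triangle surface with optional named per-vertex scalar fields."""

    vertices: np.ndarray  # (n, 3) float, mm
    triangles: np.ndarray  # (m, 3) int
    vertex_fields: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        for k, v in list(self.vertex_fields.items()):
            v = np.asarray(v, dtype=float)
            if v.shape[0] != len(self.vertices):
                raise GeometryError(f"field {k!r} length != vertex count")
            self.vertex_fields[k] = v

    # -- conversions --------------------------------------------------------
    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.triangles.copy(), process=False
        )

    @classmethod
    def from_trimesh(cls, m: trimesh.Trimesh, fields: dict | None = None) -> "TriSurface":
        return cls(np.asarray(m.vertices), np.asarray(m.faces), dict(fields or {}))

    def copy(self) -> "TriSurface":
        return TriSurface(
            self.vertices.copy(),
            self.triangles.copy(),
            {k: v.copy() for k, v in self.vertex_fields.items()},
        )

    # -- measures -----------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def area(self) -> float:
        return float(self.as_trimesh().area)

    def edge_lengths(self) -> np.ndarray:
        v, t = self.vertices, self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e = np.unique(np.sort(e, axis=1), axis=0)
        return np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1)


def extract_surface(lm: LabelMapVolume, smooth_sigma: float = 1.0) -> TriSurface:
    """Marching-cubes 0.5-isosurface of a binary volume, in mm coordinates.

    The binary volume is pre-smoothed with a Gaussian of ``smooth_sigma``
    voxels so the isosurface interpolates the voxelized boundary instead of
    tracing its staircase (which would overestimate surface area).  If the
    label is too small to survive smoothing (e.g. a single voxel) the raw
    binary volume is used instead.  Where the label touches the first or last
    slice along an axis the surface is open there.
    """
    lm.require_nonempty()
    vol = lm.voxels.astype(np.float32)
    if smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter

        sm = gaussian_filter(vol, sigma=smooth_sigma, mode="nearest")
        if sm.max() > 0.55 and sm.min() < 0.45:
            vol = sm
    verts, faces, _, _ = _skmeasure.marching_cubes(
        vol, level=0.5, spacing=lm.spacing, method="lewiner"
    )
    verts = verts + np.asarray(lm.origin)
    m = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    # orient outward: marching_cubes (lewiner) normals follow the gradient;
    # fix orientation explicitly via signed volume when the surface is closed
    if m.is_watertight and m.volume < 0:
        m.invert()
    return TriSurface.from_trimesh(m)


def smooth_surface(s: TriSurface, iterations: int) -> TriSurface:
    """Taubin (lambda-mu) smoothing with an explicit volume restoration step.

    The band-pass lambda/mu iteration removes voxelization ripple with far
    less shrinkage than plain Laplacian smoothing; the small residual
    shrinkage is compensated by a first-order normal offset so the enclosed
    volume is preserved.  ``iterations=0`` returns the surface unchanged.
    """
    if iterations < 0:
        raise GeometryError("iterations must be >= 0")
    if iterations == 0:
        return s.copy()
    m = s.as_trimesh()
    trimesh.smoothing.filter_taubin(m, lamb=0.33, nu=-0.34, iterations=iterations)
    out = TriSurface.from_trimesh(m, s.vertex_fields)
    restore_volume(out, enclosed_volume(s))
    return out


def restore_volume(s: TriSurface, vol_ref: float, max_iter: int = 3) -> None:
    """Offset interior vertices along their normals so the signed enclosed
    volume matches ``vol_ref`` (first-order correction, in place).

    Moving vertices along the winding normal by delta adds delta*area to the
    signed volume, so no orientation fix-up is needed.  Boundary vertices of
    open surfaces are left untouched.
    """
    bverts = {int(v) for loop in boundary_loops(s) for v in loop}
    interior = np.ones(s.n_vertices, dtype=bool)
    for b in bverts:
        interior[b] = False
    for _ in range(max_iter):
        dv = vol_ref - enclosed_volume(s)
        area = s.area()
        if area == 0 or abs(dv) / max(abs(vol_ref), 1e-12) < 1e-4:
            break
        vn = vertex_normals(s)
        s.vertices[interior] += (dv / area) * vn[interior]


# -- topology helpers -------------------------------------------------------

def _edge_counts(triangles: np.ndarray):
    e = np.vstack(
        [triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]]
    )
    key = np.sort(e, axis=1)
    uniq, counts = np.unique(key, axis=0, return_counts=True)
    return uniq, counts


def is_closed(s: TriSurface) -> bool:
    """True iff every edge is shared by exactly two triangles."""
    if len(s.triangles) == 0:
        return False
    _, counts = _edge_counts(s.triangles)
    return bool((counts == 2).all())


def boundary_loops(s: TriSurface) -> list[np.ndarray]:
    """Ordered vertex-index loops of the open boundary (empty if closed)."""
    uniq, counts = _edge_counts(s.triangles)
    bedges = uniq[counts == 1]
    if len(bedges) == 0:
        return []
    # walk the boundary graph (every boundary vertex has exactly 2 boundary
    # edges on a manifold-with-boundary surface)
    adj: dict[int, list[int]] = {}
    for a, b in bedges:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    seen: set[int] = set()
    loops = []
    for start in adj:
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        prev, cur = None, start
        while True:
            nxts = [v for v in adj[cur] if v != prev]
            if not nxts:
                break
            nxt = nxts[0]
            if nxt == start:
                break
            loop.append(nxt)
            seen.add(nxt)
            prev, cur = cur, nxt
        loops.append(np.asarray(loop, dtype=np.int64))
    return loops


def enclosed_volume(s: TriSurface) -> float:
    """Signed enclosed volume (mm^3); open boundary loops are closed with
    centroid fans before integrating, so open tubes get their natural volume."""
    v = s.vertices
    tris = [s.triangles]
    verts = [v]
    n = len(v)
    # directed boundary edges as they appear in the surface triangles
    t = s.triangles
    directed = set()
    e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    key = np.sort(e, axis=1)
    uniq, counts = np.unique(key, axis=0, return_counts=True)
    bset = {tuple(x) for x in uniq[counts == 1]}
    for a, b in e:
        if (min(a, b), max(a, b)) in bset:
            directed.add((int(a), int(b)))
    for loop in boundary_loops(s):
        # a closing cap must traverse each boundary edge opposite to the
        # surface triangle that owns it, so the combined shell is consistent
        if (int(loop[0]), int(loop[1 % len(loop)])) in directed:
            loop = loop[::-1]
        c = v[loop].mean(axis=0)
        verts.append(c[None, :])
        fan = np.stack(
            [loop, np.roll(loop, -1), np.full(len(loop), n, dtype=np.int64)], axis=1
        )
        tris.append(fan)
        n += 1
    vv = np.vstack(verts)
    tt = np.vstack(tris)
    a, b, c = vv[tt[:, 0]], vv[tt[:, 1]], vv[tt[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


class NearestPointLocator:
    """Nearest point on a triangulated surface, for batches of query points.

    Candidate triangles come from a KD-tree over triangle centroids; exact
    point-triangle distances are evaluated on the candidates.  Reliable when
    triangle sizes do not vary by orders of magnitude (true for extracted and
    remeshed surfaces here).
    """

    def __init__(self, surface: TriSurface, k: int = 16):
        from scipy.spatial import cKDTree

        v, f = surface.vertices, surface.triangles
        self._tris = v[f]  # (m, 3, 3)
        self._tree = cKDTree(self._tris.mean(axis=1))
        self._k = k

    def query(
        self, pts: np.ndarray, return_index: bool = False
    ) -> tuple[np.ndarray, ...]:
        """Return (closest points, distances[, triangle indices]) for (n, 3)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        k = min(self._k, len(self._tris))
        _, idx = self._tree.query(pts, k=k)
        idx = idx.reshape(len(pts), k)
        cand = self._tris[idx.ravel()]
        q = np.repeat(pts, k, axis=0)
        closest = trimesh.triangles.closest_point(cand, q).reshape(len(pts), k, 3)
        d = np.linalg.norm(closest - pts[:, None, :], axis=2)
        best = np.argmin(d, axis=1)
        ar = np.arange(len(pts))
        if return_index:
            return closest[ar, best], d[ar, best], idx[ar, best]
        return closest[ar, best], d[ar, best]


def vertex_normals(s: TriSurface) -> np.ndarray:
    """Angle-weighted per-vertex normals (unit vectors)."""
    v, t = s.vertices, s.triangles
    p0, p1, p2 = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    fn = np.cross(p1 - p0, p2 - p0)
    nrm = np.linalg.norm(fn, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    fnu = fn / nrm

    def corner_angle(a, b, c):
        u, w = b - a, c - a
        cu = np.linalg.norm(np.cross(u, w), axis=1)
        du = np.einsum("ij,ij->i", u, w)
        return np.arctan2(cu, du)

    ang = np.stack(
        [
            corner_angle(p0, p1, p2),
            corner_angle(p1, p2, p0),
            corner_angle(p2, p0, p1),
        ],
        axis=1,
    )
    out = np.zeros_like(v)
    for k in range(3):
        np.add.at(out, t[:, k], fnu * ang[:, k : k + 1])
    ln = np.linalg.norm(out, axis=1, keepdims=True)
    ln[ln == 0] = 1.0
    return out / ln
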