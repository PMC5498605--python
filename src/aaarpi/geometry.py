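"""Analysis-surface construction for the aneurysm wall and thrombus.

From the remeshed boundary of the (AAA minus lumen) solid this module builds
the three analysis surfaces — external wall, internal wall (inward offset of
the external wall by the local thickness), and the luminal surface of the
intraluminal thrombus (ILT) — plus the ILT thickness field, end caps, and the
element-size field driving the volumetric mesher.

All surfaces are in world mm coordinates with the label-map origin as datum.
Each closed/open surface is oriented outward from the solid it bounds: the
external wall away from the vessel, the luminal surface away from the lumen
(i.e. into the thrombus).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .labelmap import LabelMapVolume, subtract_lumen  # re-export subtract_lumen
from .surface import (
    NearestPointLocator,
    TriSurface,
    boundary_loops,
    enclosed_volume,
    is_closed,
    vertex_normals,
)

__all__ = [
    "AaaGeometry",
    "SizeField",
    "subtract_lumen",
    "separate_surfaces",
    "offset_internal_wall",
    "enforce_min_ilt_thickness",
    "compute_ilt_thickness",
    "build_size_field",
    "build_end_caps",
    "region_shell",
    "build_geometry",
]


@dataclass
class AaaGeometry:
    """The analysis surfaces and per-vertex fields of one case."""

    external_wall: TriSurface
    internal_wall: TriSurface  # same triangulation as external_wall
    ilt_luminal: TriSurface | None
    caps: dict  # (region, end) -> TriSurface, e.g. ("wall", "proximal")
    wall_thickness: np.ndarray  # mm, on external/internal wall vertices
    ilt_thickness: np.ndarray  # mm, on internal wall vertices

    def has_ilt(self) -> bool:
        return self.ilt_luminal is not None


@dataclass
class SizeField:
    """Element sizes (mm) on a structured lattice covering the geometry."""

    origin: np.ndarray  # (3,) mm
    spacing: float  # mm, lattice pitch (1 mm by default)
    sizes: np.ndarray  # (nx, ny, nz) > 0
    n_layers: int  # requested element layers across the wall
    ilt_interior_growth: float

    def sample(self, pts: np.ndarray) -> np.ndarray:
        """Nearest-lattice-point lookup of the size at world points (n, 3)."""
        idx = np.rint((np.atleast_2d(pts) - self.origin) / self.spacing).astype(int)
        shp = np.asarray(self.sizes.shape)
        idx = np.clip(idx, 0, shp - 1)
        return self.sizes[idx[:, 0], idx[:, 1], idx[:, 2]]


def separate_surfaces(shell: TriSurface) -> tuple[TriSurface, TriSurface | None]:
    """Split the shell boundary into (external wall, luminal surface or None).

    The connected component enclosing the largest absolute volume is the
    external wall; the remaining component (if any) is the luminal ILT
    surface.  More than two components indicate non-simple topology and are
    rejected.  The luminal surface is re-oriented outward with respect to the
    lumen it encloses (normals pointing into the thrombus).
    """
    m = shell.as_trimesh()
    parts = m.split(only_watertight=False)
    if len(parts) == 0:
        raise GeometryError("empty shell surface")
    if len(parts) > 2:
        raise GeometryError(
            f"expected at most 2 surface components, found {len(parts)}"
        )
    surfs = [TriSurface.from_trimesh(p) for p in parts]
    vols = [enclosed_volume(s) for s in surfs]
    order = np.argsort([-abs(v) for v in vols])
    external = surfs[order[0]]
    if enclosed_volume(external) < 0:
        external = TriSurface(external.vertices, external.triangles[:, ::-1])
    if len(surfs) == 1:
        return external, None
    luminal = surfs[order[1]]
    if enclosed_volume(luminal) < 0:
        luminal = TriSurface(luminal.vertices, luminal.triangles[:, ::-1])
    return external, luminal


def offset_internal_wall(
    external: TriSurface, thickness: np.ndarray
) -> TriSurface:
    """Internal wall surface: external vertices moved inward by the local
    thickness along angle-weighted vertex normals; connectivity unchanged.

    Fold-over (a triangle whose normal flips after the offset) indicates the
    offset self-intersects locally and raises an error listing the vertices
    involved; it is not silently repaired.
    """
    thickness = np.asarray(thickness, dtype=float)
    if thickness.shape[0] != external.n_vertices:
        raise GeometryError("thickness field length != vertex count")
    if (thickness <= 0).any():
        raise GeometryError("wall thickness must be positive everywhere")
    n = vertex_normals(external)
    v_new = external.vertices - n * thickness[:, None]
    t = external.triangles
    n_old = np.cross(
        external.vertices[t[:, 1]] - external.vertices[t[:, 0]],
        external.vertices[t[:, 2]] - external.vertices[t[:, 0]],
    )
    n_new = np.cross(v_new[t[:, 1]] - v_new[t[:, 0]], v_new[t[:, 2]] - v_new[t[:, 0]])
    flipped = np.einsum("ij,ij->i", n_old, n_new) <= 0
    if flipped.any():
        bad = np.unique(t[flipped].ravel())
        raise GeometryError(
            f"inward offset self-intersects at {len(bad)} vertices "
            f"(first few: {bad[:8].tolist()})"
        )
    out = TriSurface(v_new, t.copy(), dict(external.vertex_fields))
    # global inversion (offset exceeding the inradius turns a closed surface
    # inside out without flipping any individual triangle)
    if is_closed(external):
        v0, v1 = enclosed_volume(external), enclosed_volume(out)
        if v0 * v1 <= 0:
            raise GeometryError("offset exceeds the local feature size (inverted surface)")
    return out


def enforce_min_ilt_thickness(
    internal_wall: TriSurface,
    ilt_luminal: TriSurface,
    min_thickness: float = 1.0,
) -> TriSurface:
    """Push luminal vertices away from the wall until the ILT layer is at
    least ``min_thickness`` everywhere; compliant vertices are untouched.

    The luminal surface (not the wall) is modified.  Each violating vertex
    moves along the wall-to-vertex direction to ``min_thickness`` from its
    nearest wall point; a few passes handle vertices whose nearest wall point
    changes after the push.  If the push would invert the luminal surface the
    lumen is too small for the requested layer and an error is raised.
    """
    if min_thickness < 0:
        raise GeometryError("min_thickness must be >= 0")
    loc = NearestPointLocator(internal_wall)
    v = ilt_luminal.vertices.copy()
    moved = np.zeros(len(v), dtype=bool)
    # The wall surface is oriented away from the lumen (same winding as the
    # external wall), so its facet normals give a signed side: positive means
    # a luminal vertex strayed through the undulating wall.  Violators are
    # placed directly on the lumen side of their nearest wall point, slightly
    # past the target so the piecewise-linear surface (triangle interiors,
    # not just vertices) clears the minimum too.
    wt = internal_wall.triangles
    wv = internal_wall.vertices
    fn = np.cross(
        wv[wt[:, 1]] - wv[wt[:, 0]], wv[wt[:, 2]] - wv[wt[:, 0]]
    )
    fn /= np.linalg.norm(fn, axis=1, keepdims=True)
    push_to = min_thickness * 1.02
    # clamp to the vessel's axial extent: near the cut ends the nearest wall
    # point lies on the wall's open edge and unconstrained pushes would let
    # boundary vertices creep past the end of the vessel
    z_lo, z_hi = v[:, 2].min(), v[:, 2].max()
    for _ in range(10):
        closest, d, tri_idx = loc.query(v, return_index=True)
        side = np.einsum("ij,ij->i", v - closest, fn[tri_idx])
        signed = np.where(side >= 0, d, -d)  # positive = outside the lumen side
        viol = signed > -min_thickness * (1.0 - 1e-9)
        if not viol.any():
            break
        v[viol] = closest[viol] - fn[tri_idx[viol]] * push_to
        v[viol, 2] = np.clip(v[viol, 2], z_lo, z_hi)
        moved[viol] = True
    else:
        raise GeometryError("minimum ILT thickness enforcement did not converge")
    out = TriSurface(v, ilt_luminal.triangles.copy(), dict(ilt_luminal.vertex_fields))
    vol_old, vol_new = enclosed_volume(ilt_luminal), enclosed_volume(out)
    if vol_new <= 0 or (vol_old > 0 and vol_new > vol_old * (1 + 1e-9)):
        raise GeometryError(
            "lumen too small to guarantee the minimum ILT thickness"
        )
    return out


def compute_ilt_thickness(
    internal_wall: TriSurface, ilt_luminal: TriSurface | None
) -> np.ndarray:
    """Per internal-wall-vertex distance (mm) to the nearest luminal point.

    Absent luminal surface (no thrombus) gives the zero field.
    """
    if ilt_luminal is None:
        return np.zeros(internal_wall.n_vertices)
    loc = NearestPointLocator(ilt_luminal)
    _, d = loc.query(internal_wall.vertices)
    return d


def build_size_field(
    geom: AaaGeometry,
    n_layers: int = 2,
    ilt_interior_growth: float = 3.0,
    lattice_spacing: float = 1.0,
) -> SizeField:
    """Element-size lattice: wall thickness / n_layers near the wall, growing
    toward the ILT mid-layer by ``ilt_interior_growth``.

    The lattice covers the bounding box of the external wall at 1 mm pitch.
    At a lattice point the size interpolates between the near-wall size
    (local thickness / n_layers) and the near-lumen size, inflated in the ILT
    interior by a sine bump peaking at the mid-layer.
    """
    if n_layers < 1:
        raise GeometryError("n_layers must be >= 1")
    if ilt_interior_growth < 1:
        raise GeometryError("ilt_interior_growth must be >= 1")
    ext = geom.external_wall
    lo = ext.vertices.min(axis=0) - 2.0
    hi = ext.vertices.max(axis=0) + 2.0
    shape = np.maximum(np.ceil((hi - lo) / lattice_spacing).astype(int) + 1, 2)
    axes = [lo[i] + lattice_spacing * np.arange(shape[i]) for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    from scipy.spatial import cKDTree

    loc_ext = NearestPointLocator(geom.external_wall, k=6)
    loc_int = NearestPointLocator(geom.internal_wall, k=6)
    wall_tree = cKDTree(geom.internal_wall.vertices)
    th = np.asarray(geom.wall_thickness, dtype=float)
    loc_lum = NearestPointLocator(geom.ilt_luminal, k=6) if geom.has_ilt() else None
    if loc_lum is not None:
        lum_el = geom.ilt_luminal.edge_lengths()
        lum_size = float(np.median(lum_el))

    sizes = np.empty(len(pts))
    band = lattice_spacing * np.sqrt(3.0) / 2.0  # lattice quantization slack
    for s0 in range(0, len(pts), 65536):
        sl = slice(s0, min(s0 + 65536, len(pts)))
        p = pts[sl]
        _, d_ext = loc_ext.query(p)
        _, d_int = loc_int.query(p)
        _, idx = wall_tree.query(p)
        local_th = th[idx]
        wall_size = local_th / n_layers
        near_wall = (d_ext + d_int) <= local_th + 2 * band
        chunk = np.empty(len(p))
        chunk[near_wall] = wall_size[near_wall]
        rest = ~near_wall
        if loc_lum is not None and rest.any():
            _, d_lum = loc_lum.query(p[rest])
            denom = d_int[rest] + d_lum
            denom[denom == 0] = 1.0
            xi = np.clip(d_int[rest] / denom, 0.0, 1.0)  # 0 wall -> 1 lumen
            base = wall_size[rest] * (1 - xi) + lum_size * xi
            chunk[rest] = base * (
                1.0 + (ilt_interior_growth - 1.0) * np.sin(np.pi * xi)
            )
        elif rest.any():
            chunk[rest] = wall_size[rest]
        sizes[sl] = chunk
    sizes = np.maximum(sizes, 1e-3)
    return SizeField(
        origin=lo,
        spacing=lattice_spacing,
        sizes=sizes.reshape(shape),
        n_layers=n_layers,
        ilt_interior_growth=float(ilt_interior_growth),
    )


def _pair_loops_by_end(loops_a, verts_a, loops_b, verts_b, axis: int = 2):
    """Pair boundary loops of two surfaces by their axial position."""
    za = [float(np.mean(verts_a[l][:, axis])) for l in loops_a]
    zb = [float(np.mean(verts_b[l][:, axis])) for l in loops_b]
    pairs = []
    used = set()
    for i, z in enumerate(za):
        j = int(np.argmin([abs(z - w) if k not in used else np.inf for k, w in enumerate(zb)]))
        if np.isinf(abs(z - zb[j])):
            raise GeometryError("boundary loops not pairable")
        used.add(j)
        pairs.append((loops_a[i], loops_b[j], z))
    return pairs


def _zip_loops(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Triangulate the annular band between two 3D loops (point arrays).

    Both loops are parameterized by angle around their common centroid in the
    best-fit cap plane and merged; returns (m, 3) indices into the stacked
    array [pa; pb].
    """
    c = np.vstack([pa, pb]).mean(axis=0)
    # cap plane basis from the loop with more points
    ref = pa if len(pa) >= len(pb) else pb
    d = ref - c
    u, s, vt = np.linalg.svd(d - d.mean(axis=0), full_matrices=False)
    e1, e2 = vt[0], vt[1]

    def angles(p):
        q = p - c
        return np.arctan2(q @ e2, q @ e1)

    ta, tb = angles(pa), angles(pb)
    oa = np.argsort(ta)
    ob = np.argsort(tb)
    na, nb = len(pa), len(pb)
    tris = []
    i = j = 0
    sa = ta[oa]
    sb = tb[ob]
    # merge walk around the circle
    total = na + nb
    for _ in range(total):
        ia, ia1 = oa[i % na], oa[(i + 1) % na]
        ib, ib1 = ob[j % nb], ob[(j + 1) % nb]
        next_a = sa[(i + 1) % na] + (2 * np.pi if i + 1 >= na else 0)
        next_b = sb[(j + 1) % nb] + (2 * np.pi if j + 1 >= nb else 0)
        if (next_a <= next_b and i < na) or j >= nb:
            tris.append((ia, ia1, na + ib))
            i += 1
        else:
            tris.append((ia, na + ib1, na + ib))
            j += 1
        if i >= na and j >= nb:
            break
    return np.asarray(tris, dtype=np.int64)


def build_end_caps(geom: AaaGeometry) -> dict:
    """Planar ring caps closing the wall annulus (and the ILT annulus when a
    thrombus exists) at the proximal and distal vessel ends.

    Returns {(region, end): TriSurface}; ``end`` is "proximal" (low z) or
    "distal".  Cap normals are oriented outward (axially) from each region.
    """
    ext, internal = geom.external_wall, geom.internal_wall
    loops_e = boundary_loops(ext)
    if len(loops_e) != 2:
        raise GeometryError(
            f"expected 2 open ends on the external wall, found {len(loops_e)}"
        )
    caps: dict = {}

    def add_cap(region, name, pa, pb, outward_sign):
        tris = _zip_loops(pa, pb)
        verts = np.vstack([pa, pb])
        cap = TriSurface(verts, tris)
        # orient: cap normal should point along outward_sign * z
        nrm = np.cross(
            verts[tris[:, 1]] - verts[tris[:, 0]],
            verts[tris[:, 2]] - verts[tris[:, 0]],
        ).sum(axis=0)
        if nrm[2] * outward_sign < 0:
            cap = TriSurface(verts, tris[:, ::-1])
        caps[(region, name)] = cap

    # wall caps: external and internal walls share connectivity, so the same
    # loop indices apply to both vertex arrays
    zs = [float(np.mean(ext.vertices[l][:, 2])) for l in loops_e]
    names = ["proximal", "distal"] if zs[0] <= zs[1] else ["distal", "proximal"]
    for loop, name in zip(loops_e, names):
        sign = -1.0 if name == "proximal" else 1.0
        add_cap("wall", name, ext.vertices[loop], internal.vertices[loop], sign)

    if geom.has_ilt():
        loops_l = boundary_loops(geom.ilt_luminal)
        if len(loops_l) != 2:
            raise GeometryError(
                f"expected 2 open ends on the luminal surface, found {len(loops_l)}"
            )
        zl = [float(np.mean(geom.ilt_luminal.vertices[l][:, 2])) for l in loops_l]
        for loop, name in zip(loops_e, names):
            z = float(np.mean(ext.vertices[loop][:, 2]))
            j = int(np.argmin([abs(z - w) for w in zl]))
            sign = -1.0 if name == "proximal" else 1.0
            add_cap(
                "ilt",
                name,
                internal.vertices[loop],
                geom.ilt_luminal.vertices[loops_l[j]],
                sign,
            )
    return caps


def region_shell(geom: AaaGeometry, region: str) -> TriSurface:
    """Closed boundary shell of one region ("wall" or "ilt"), outward-oriented,
    assembled from the analysis surfaces and the end caps (duplicate vertices
    welded).  Used for watertightness checks and as mesher input."""
    import trimesh

    if region == "wall":
        parts = [
            geom.external_wall,
            TriSurface(geom.internal_wall.vertices, geom.internal_wall.triangles[:, ::-1]),
        ]
    elif region == "ilt":
        if not geom.has_ilt():
            raise GeometryError("no ILT region in this geometry")
        parts = [
            geom.internal_wall,
            TriSurface(geom.ilt_luminal.vertices, geom.ilt_luminal.triangles[:, ::-1]),
        ]
    else:
        raise GeometryError(f"unknown region {region!r}")
    parts += [s for (reg, _), s in geom.caps.items() if reg == region]
    vs, fs, off = [], [], 0
    for p in parts:
        vs.append(p.vertices)
        fs.append(p.triangles + off)
        off += len(p.vertices)
    m = trimesh.Trimesh(vertices=np.vstack(vs), faces=np.vstack(fs), process=True)
    m.merge_vertices()
    return TriSurface.from_trimesh(m)


def build_geometry(
    aaa: LabelMapVolume,
    lumen: LabelMapVolume | None,
    thickness_of,
    target_edge: float = 3.0,
    min_ilt_thickness: float = 1.0,
    n_layers: int = 2,
    ilt_interior_growth: float = 3.0,
) -> tuple[AaaGeometry, SizeField]:
    """Full geometry stage: label maps -> analysis surfaces + size field.

    ``thickness_of`` maps an external-wall TriSurface to a per-vertex
    thickness field (constant or interpolated from sparse measurements).
    """
    from .remesh import remesh_uniform
    from .surface import extract_surface

    shell_lm = subtract_lumen(aaa, lumen) if lumen is not None else aaa
    raw = extract_surface(shell_lm)
    external, luminal = separate_surfaces(raw)
    external = remesh_uniform(external, target_edge)
    if luminal is not None:
        luminal = remesh_uniform(luminal, target_edge)
    wall_th = np.asarray(thickness_of(external), dtype=float)
    if wall_th.ndim == 0:
        wall_th = np.full(external.n_vertices, float(wall_th))
    internal = offset_internal_wall(external, wall_th)
    if luminal is not None:
        luminal = enforce_min_ilt_thickness(internal, luminal, min_ilt_thickness)
    ilt_th = compute_ilt_thickness(internal, luminal)
    external.vertex_fields["thickness"] = wall_th
    internal.vertex_fields["thickness"] = wall_th
    internal.vertex_fields["ilt_thickness"] = ilt_th
    geom = AaaGeometry(
        external_wall=external,
        internal_wall=internal,
        ilt_luminal=luminal,
        caps={},
        wall_thickness=wall_th,
        ilt_thickness=ilt_th,
    )
    geom.caps = build_end_caps(geom)
    sf = build_size_field(geom, n_layers, ilt_interior_growth)
    return geom, sf
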