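"""Conforming tetrahedral meshing of the wall and thrombus regions.

The wall is a thin shell between two surfaces with identical connectivity
(the internal wall is the inward offset of the external wall), and the
thrombus (ILT) sits between the internal wall and the luminal surface.  The
mesher exploits this: each surface triangle is extruded into a column of
prisms across the thickness, and every prism is split into three tetrahedra
with globally consistent quad diagonals (lowest-global-index rule), which
guarantees a conforming mesh — the wall and ILT regions share the internal
wall nodes exactly, transmitting load without tie constraints.

The element-size field controls the number of element layers across the wall
(local thickness / near-wall size) and the graded layer spacing inside the
ILT (coarser at the mid-layer, finer at both boundary surfaces).  In-plane
(lateral) resolution is inherited from the remeshed surfaces and is
deliberately decoupled from the through-thickness size so problem sizes stay
tractable; see the methods note.

Meshes are written/read as legacy ASCII ``.vtk`` unstructured grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MeshError
from .geometry import AaaGeometry, SizeField
from .surface import NearestPointLocator, TriSurface, boundary_loops

__all__ = [
    "TetMesh",
    "mesh_regions",
    "quality_report",
    "extrude_shell",
    "count_wall_layers",
]

# edge order for 10-node tets: nodes 4..9 are midpoints of these corner pairs
TET10_EDGES = [(0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3)]


@dataclass
class TetMesh:
    """Tetrahedral mesh with region tags and named boundary entities.

    ``tets`` is (m, 4) for linear elements or (m, 10) for quadratic ones
    (corner nodes first, then mid-edge nodes in :data:`TET10_EDGES` order).
    ``facet_sets`` holds boundary facets as corner-node triangles (k, 3) or
    quadratic facets (k, 6); ``node_sets`` holds node-index arrays.
    """

    nodes: np.ndarray
    tets: np.ndarray
    region_tags: np.ndarray  # per-tet: "wall" | "ilt"
    facet_sets: dict[str, np.ndarray] = field(default_factory=dict)
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def order(self) -> int:
        return 1 if self.tets.shape[1] == 4 else 2

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def volumes(self) -> np.ndarray:
        t = self.tets[:, :4]
        a, b, c, d = (self.nodes[t[:, i]] for i in range(4))
        return np.einsum("ij,ij->i", b - a, np.cross(c - a, d - a)) / 6.0

    def region_volume(self, region: str) -> float:
        return float(self.volumes()[self.region_tags == region].sum())

    def wall_nodes(self) -> np.ndarray:
        """Node indices touched by wall elements."""
        return np.unique(self.tets[self.region_tags == "wall"].ravel())


def _split_prism(bot: np.ndarray, top: np.ndarray) -> list[tuple]:
    """Split one prism (bottom triangle ``bot``, top ``top``, matched order)
    into 3 tets using the lowest-global-index diagonal rule.

    Bottom indices are always lower than top indices here (layer-major node
    numbering), so every quad diagonal runs from a bottom vertex to a top
    vertex and the decomposition below covers all diagonal choices.
    """
    a, b, c = bot
    A, B, C = top
    # rotate so the smallest bottom index comes first
    order = np.argsort([a, b, c])
    if order[0] == 1:
        a, b, c, A, B, C = b, c, a, B, C, A
    elif order[0] == 2:
        a, b, c, A, B, C = c, a, b, C, A, B
    # quads: (a,b,B,A) diag a-B; (a,c,C,A) diag a-C; (b,c,C,B) diag by min(b,c)
    if b < c:
        return [(a, b, c, C), (a, b, C, B), (a, B, C, A)]
    return [(a, b, c, B), (a, B, c, C), (a, B, C, A)]


def extrude_shell(
    surface: TriSurface,
    sheets: list[np.ndarray],
    node_offset: int = 0,
    base_ids: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Extrude ``surface`` connectivity through a list of vertex sheets.

    ``sheets[k]`` is the (n_v, 3) vertex array of layer k.  Returns
    ``(new_nodes, tets)`` where tets reference global node ids: layer 0 uses
    ``base_ids`` when given (for conforming stacking onto an existing mesh),
    later layers are numbered consecutively from ``node_offset``.
    """
    nv = surface.n_vertices
    tris = surface.triangles
    n_sheets = len(sheets)
    ids = []
    new_nodes = []
    nid = node_offset
    for k in range(n_sheets):
        if k == 0 and base_ids is not None:
            ids.append(np.asarray(base_ids, dtype=np.int64))
        else:
            ids.append(np.arange(nid, nid + nv, dtype=np.int64))
            new_nodes.append(sheets[k])
            nid += nv
    tets = []
    for k in range(n_sheets - 1):
        lo, hi = ids[k], ids[k + 1]
        for tri in tris:
            bot = lo[tri]
            top = hi[tri]
            tets.extend(_split_prism(bot, top))
    nodes = np.vstack(new_nodes) if new_nodes else np.empty((0, 3))
    return nodes, np.asarray(tets, dtype=np.int64)


def _ray_first_hit(origins: np.ndarray, dirs: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Distance to the first triangle hit per ray (inf on miss).

    Vectorized Möller–Trumbore over all triangles, chunked over rays.
    ``tris`` has shape (m, 3, 3).
    """
    n = len(origins)
    tmin = np.full(n, np.inf)
    v0, v1, v2 = tris[:, 0], tris[:, 1], tris[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    for s in range(0, n, 256):
        sl = slice(s, min(s + 256, n))
        o, d = origins[sl], dirs[sl]
        h = np.cross(d[:, None, :], e2[None, :, :])
        a = np.einsum("mj,nmj->nm", e1, h)
        mask = np.abs(a) > 1e-12
        f = np.where(mask, 1.0 / np.where(mask, a, 1.0), 0.0)
        sv = o[:, None, :] - v0[None, :, :]
        u = f * np.einsum("nmj,nmj->nm", sv, h)
        q = np.cross(sv, e1[None, :, :])
        v = f * np.einsum("nj,nmj->nm", d, q)
        t = f * np.einsum("mj,nmj->nm", e2, q)
        ok = (
            mask
            & (u >= -1e-9)
            & (u <= 1 + 1e-9)
            & (v >= -1e-9)
            & (u + v <= 1 + 1e-9)
            & (t > 1e-9)
        )
        tmin[sl] = np.where(ok, t, np.inf).min(axis=1)
    return tmin


def _map_luminal_sheet(internal: TriSurface, luminal: TriSurface) -> np.ndarray:
    """Map each internal-wall vertex to a point on the luminal surface.

    Columns aim at the local lumen centerline (cross-section centroid at the
    vertex's height), the natural O-grid mapping for tubular anatomy: it
    avoids the column clustering a plain nearest-point map produces when the
    lumen is eccentric.  A ray hit is accepted only within a window around
    the nearest-point distance (near-tangent rays at the cut ends can slip
    past the open boundary and strike the far side); rejected or missed rays
    fall back to the nearest point.  Boundary columns are pinned to the
    luminal boundary rings so the cut ends stay planar.
    """
    lv = luminal.vertices
    zq = internal.vertices[:, 2]
    nz = 40
    zbins = np.linspace(lv[:, 2].min(), lv[:, 2].max(), nz + 1)
    which = np.clip(np.digitize(lv[:, 2], zbins) - 1, 0, nz - 1)
    zc, cx = [], []
    for k in range(nz):
        sel = which == k
        if sel.any():
            zc.append(0.5 * (zbins[k] + zbins[k + 1]))
            cx.append(lv[sel, :2].mean(axis=0))
    zc = np.asarray(zc)
    cx = np.asarray(cx)
    center = np.column_stack(
        [np.interp(zq, zc, cx[:, 0]), np.interp(zq, zc, cx[:, 1]), zq]
    )
    dirs = center - internal.vertices
    nrm = np.linalg.norm(dirs, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    dirs = dirs / nrm
    t = _ray_first_hit(internal.vertices, dirs, lv[luminal.triangles])

    loc = NearestPointLocator(luminal)
    nearest, d_n = loc.query(internal.vertices)
    accept = np.isfinite(t) & (t <= np.maximum(3.0 * d_n, d_n + 3.0))
    t_ok = np.where(np.isfinite(t), t, 0.0)
    target = np.where(
        accept[:, None], internal.vertices + dirs * t_ok[:, None], nearest
    )

    # pin boundary columns to the luminal boundary ring polylines, using the
    # same ray-toward-centerline direction as the interior columns (in the
    # cap plane) so the end columns do not shear against their neighbours
    lum_loops = boundary_loops(luminal)
    wall_loops = boundary_loops(internal)
    if lum_loops and wall_loops:
        ring_pts = [lv[l] for l in lum_loops]
        ring_z = [float(p[:, 2].mean()) for p in ring_pts]
        for vtx in np.concatenate(wall_loops):
            p = internal.vertices[vtx]
            ring = ring_pts[int(np.argmin([abs(p[2] - z) for z in ring_z]))]
            c2 = center[vtx, :2]
            hit = _ray_ring_intersection(p[:2], c2 - p[:2], ring[:, :2])
            if hit is not None:
                target[vtx] = np.array([hit[0], hit[1], float(np.mean(ring[:, 2]))])
                continue
            nxt = np.roll(ring, -1, axis=0)
            ab = nxt - ring
            denom = np.einsum("ij,ij->i", ab, ab)
            denom[denom == 0] = 1.0
            tpar = (
                np.clip(
                    np.einsum("ij,j->i", ab, p) - np.einsum("ij,ij->i", ab, ring),
                    0,
                    denom,
                )
                / denom
            )
            proj = ring + ab * tpar[:, None]
            target[vtx] = proj[np.argmin(np.linalg.norm(proj - p, axis=1))]
    return target


def _ray_ring_intersection(origin, direction, ring_xy):
    """First intersection of a 2D ray with a closed polyline (None if none)."""
    d = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(d)
    if nrm == 0:
        return None
    d = d / nrm
    a = ring_xy
    b = np.roll(ring_xy, -1, axis=0)
    e = b - a
    # solve origin + t d = a + s e, 0<=s<=1, t>0
    denom = d[0] * (-e[:, 1]) + d[1] * e[:, 0]
    ok = np.abs(denom) > 1e-12
    ao = a - origin
    t = (ao[:, 0] * (-e[:, 1]) + ao[:, 1] * e[:, 0]) / np.where(ok, denom, 1.0)
    s = (d[0] * ao[:, 1] - d[1] * ao[:, 0]) / np.where(ok, denom, 1.0)
    valid = ok & (t > 1e-9) & (s >= -1e-9) & (s <= 1 + 1e-9)
    if not valid.any():
        return None
    ti = t[valid].min()
    return origin + ti * d


def _ilt_layer_fractions(n: int, growth: float) -> np.ndarray:
    """Cumulative layer fractions in [0, 1] with spacing growing toward the
    mid-layer by ``growth`` (sine profile), fine at both boundaries."""
    mid = (np.arange(n) + 0.5) / n
    w = 1.0 + (growth - 1.0) * np.sin(np.pi * mid)
    cum = np.concatenate([[0.0], np.cumsum(w)])
    return cum / cum[-1]


def _check_watertight(geom: AaaGeometry) -> None:
    from .geometry import region_shell
    from .surface import is_closed

    regions = ["wall"] + (["ilt"] if geom.has_ilt() else [])
    for r in regions:
        if not is_closed(region_shell(geom, r)):
            raise MeshError(f"{r} region shell is not watertight")


def mesh_regions(
    geom: AaaGeometry,
    sf: SizeField,
    order: int = 2,
    include_ilt: bool = True,
) -> TetMesh:
    """Mesh the wall (and, when present and requested, the ILT) conformingly.

    Wall layer count comes from the size field (median local thickness over
    near-wall size, at least ``sf.n_layers``); ILT layer count and grading
    come from the median ILT thickness, the boundary sizes and the interior
    growth factor.  Raises :class:`MeshError` for non-watertight input or if
    any extruded tetrahedron is inverted.
    """
    if order not in (1, 2):
        raise MeshError("element order must be 1 or 2")
    _check_watertight(geom)
    ext, internal = geom.external_wall, geom.internal_wall
    nv = ext.n_vertices
    th = np.asarray(geom.wall_thickness, dtype=float)

    # wall layer count from the size field sampled in the wall band
    probe = 0.5 * (ext.vertices + internal.vertices)
    near_size = sf.sample(probe)
    n_wall = int(max(sf.n_layers, np.round(np.median(th / near_size))))

    sheets = [
        ext.vertices + (internal.vertices - ext.vertices) * (k / n_wall)
        for k in range(n_wall + 1)
    ]
    nodes, tets = extrude_shell(ext, sheets, node_offset=0)
    region = ["wall"] * len(tets)
    sheet_ids = [np.arange(k * nv, (k + 1) * nv) for k in range(n_wall + 1)]
    internal_ids = sheet_ids[-1]

    facet_sets: dict[str, np.ndarray] = {
        "exterior_wall": ext.triangles.copy(),
        "internal_wall": internal_ids[internal.triangles],
    }

    with_ilt = include_ilt and geom.has_ilt()
    n_ilt = 0
    all_tets = [tets]
    all_nodes = [nodes]
    if with_ilt:
        ilt_th = np.asarray(geom.ilt_thickness, dtype=float)
        # luminal extrusion target: nearest point on the adjusted luminal
        # surface from each internal wall vertex
        target = _map_luminal_sheet(internal, geom.ilt_luminal)
        # a couple of smooth+reproject sweeps iron residual kinks in the
        # mapped sheet (boundary rings stay pinned)
        from .thickness import smooth_field

        loc = NearestPointLocator(geom.ilt_luminal)
        bidx = np.concatenate(boundary_loops(internal))
        interior = np.ones(nv, dtype=bool)
        interior[bidx] = False
        for _ in range(2):
            sm = target.copy()
            for dim in range(3):
                sm[:, dim] = smooth_field(internal, target[:, dim], 1)
            sm[~interior] = target[~interior]
            proj, _ = loc.query(sm[interior])
            target[interior] = proj

        lum_size = float(np.median(geom.ilt_luminal.edge_lengths()))
        wall_size = float(np.median(th)) / sf.n_layers
        growth = sf.ilt_interior_growth
        mean_spacing = 0.5 * (wall_size + lum_size) * (
            1.0 + (growth - 1.0) * 2.0 / np.pi
        )
        t_med = float(np.median(ilt_th))
        # at least 3 layers so the fine-coarse-fine grading exists; capped so
        # the thinnest columns keep usable layer heights (>= ~1/3 mm)
        col_len = np.linalg.norm(target - internal.vertices, axis=1)
        cap = max(3, int(np.floor(np.percentile(col_len, 5) / 0.33)))
        n_ilt = int(np.clip(np.round(t_med / mean_spacing), 3, cap))
        frac = _ilt_layer_fractions(n_ilt, growth)
        ilt_sheets = [
            internal.vertices + (target - internal.vertices) * f for f in frac
        ]
        ilt_nodes, ilt_tets = extrude_shell(
            internal,
            ilt_sheets,
            node_offset=(n_wall + 1) * nv,
            base_ids=internal_ids,
        )
        all_nodes.append(ilt_nodes)
        all_tets.append(ilt_tets)
        region += ["ilt"] * len(ilt_tets)
        lum_ids = np.arange((n_wall + 1) * nv + (n_ilt - 1) * nv, (n_wall + 1) * nv + n_ilt * nv)
        facet_sets["ilt_luminal"] = lum_ids[internal.triangles]

    nodes = np.vstack(all_nodes)
    tets = np.vstack(all_tets)
    region = np.asarray(region)

    # canonical positive orientation
    a, b, c, d = (nodes[tets[:, i]] for i in range(4))
    vol6 = np.einsum("ij,ij->i", b - a, np.cross(c - a, d - a))
    neg = vol6 < 0
    tets[neg] = tets[neg][:, [0, 2, 1, 3]]
    vol6 = np.abs(vol6)
    if (vol6 < 1e-12).any():
        raise MeshError(
            f"{int((vol6 < 1e-12).sum())} degenerate tetrahedra in extrusion"
        )

    # cap facets and node sets from boundary loops of the external wall
    loops = boundary_loops(ext)
    zs = [float(np.mean(ext.vertices[l][:, 2])) for l in loops]
    names = {}
    names[int(np.argmin(zs))] = "caps_bottom"
    names[int(np.argmax(zs))] = "caps_top"
    n_sheet_total = n_wall + 1
    cap_nodes: dict[str, list] = {"caps_bottom": [], "caps_top": []}
    cap_facets: dict[str, list] = {"caps_bottom": [], "caps_top": []}
    # directed boundary edges of the surface triangulation
    tsur = ext.triangles
    esur = np.vstack([tsur[:, [0, 1]], tsur[:, [1, 2]], tsur[:, [2, 0]]])
    key = np.sort(esur, axis=1)
    uniq, counts = np.unique(key, axis=0, return_counts=True)
    bkeys = {tuple(x) for x in uniq[counts == 1]}

    n_layers_all = n_wall + (n_ilt if with_ilt else 0)
    for li, loop in enumerate(loops):
        if li not in names:  # pragma: no cover - exactly two loops expected
            continue
        name = names[li]
        # layer-major numbering: global layer k occupies ids [k*nv, (k+1)*nv)
        ids_per_layer = [k * nv for k in range(n_layers_all + 1)]
        for v in loop:
            cap_nodes[name].extend(
                int(off + v) for off in ids_per_layer
            )
        for i in range(len(loop)):
            a0, b0 = int(loop[i]), int(loop[(i + 1) % len(loop)])
            if (min(a0, b0), max(a0, b0)) not in bkeys:
                continue
            for k in range(n_layers_all):
                la, lb = ids_per_layer[k], ids_per_layer[k + 1]
                quad = (la + a0, la + b0, lb + b0, lb + a0)
                # split along the diagonal from the lowest-index corner
                if min(quad[0], quad[2]) < min(quad[1], quad[3]):
                    cap_facets[name] += [
                        (quad[0], quad[1], quad[2]),
                        (quad[0], quad[2], quad[3]),
                    ]
                else:
                    cap_facets[name] += [
                        (quad[0], quad[1], quad[3]),
                        (quad[1], quad[2], quad[3]),
                    ]
    for name in ("caps_bottom", "caps_top"):
        facet_sets[name] = np.asarray(cap_facets[name], dtype=np.int64)

    node_sets = {
        "caps_bottom": np.unique(np.asarray(cap_nodes["caps_bottom"], dtype=np.int64)),
        "caps_top": np.unique(np.asarray(cap_nodes["caps_top"], dtype=np.int64)),
        "exterior_wall": np.unique(facet_sets["exterior_wall"].ravel()),
        "internal_wall": np.unique(facet_sets["internal_wall"].ravel()),
    }
    if with_ilt:
        node_sets["ilt_luminal"] = np.unique(facet_sets["ilt_luminal"].ravel())

    mesh = TetMesh(nodes, tets, region, facet_sets, node_sets)
    if order == 2:
        mesh = _elevate_order(mesh)
    return mesh


def _elevate_order(mesh: TetMesh) -> TetMesh:
    """Add mid-edge nodes (10-node tets); facet sets become 6-node facets."""
    tets = mesh.tets
    edges = np.vstack([tets[:, list(pair)] for pair in TET10_EDGES])
    key = np.sort(edges, axis=1)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    mid = 0.5 * (mesh.nodes[uniq[:, 0]] + mesh.nodes[uniq[:, 1]])
    n0 = mesh.n_nodes
    mid_ids = n0 + np.arange(len(uniq))
    new_tets = np.empty((len(tets), 10), dtype=np.int64)
    new_tets[:, :4] = tets
    per_edge = inv.reshape(6, len(tets))
    for e in range(6):
        new_tets[:, 4 + e] = mid_ids[per_edge[e]]
    edge_lookup = {(int(a), int(b)): int(i) for i, (a, b) in enumerate(uniq)}

    def facet6(tris: np.ndarray) -> np.ndarray:
        out = np.empty((len(tris), 6), dtype=np.int64)
        out[:, :3] = tris
        for j, (p, q) in enumerate([(0, 1), (1, 2), (2, 0)]):
            for i, tri in enumerate(tris):
                a, b = int(tri[p]), int(tri[q])
                out[i, 3 + j] = n0 + edge_lookup[(min(a, b), max(a, b))]
        return out

    facet_sets = {k: facet6(v) for k, v in mesh.facet_sets.items()}
    node_sets = {k: np.unique(facet_sets[k].ravel()) if k in facet_sets else v
                 for k, v in mesh.node_sets.items()}
    return TetMesh(
        np.vstack([mesh.nodes, mid]),
        new_tets,
        mesh.region_tags.copy(),
        facet_sets,
        node_sets,
    )


def count_wall_layers(
    mesh: TetMesh,
    n_probes: int = 50,
    rng: np.random.Generator | None = None,
    end_margin: float = 10.0,
) -> np.ndarray:
    """Distinct wall elements crossed along inward surface-normal probes.

    Random exterior-wall facets (away from the end caps) are probed from
    their centroid along the inward normal; the probe samples the segment
    densely and counts the distinct wall elements containing the samples.
    Every element layer contributes at least one crossed element (a layer of
    tetrahedra split from prisms typically contributes 2-3), so the count is
    a per-probe upper proxy for — and never below — the layer count.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    ext = mesh.facet_sets["exterior_wall"][:, :3]
    cent = mesh.nodes[ext].mean(axis=1)
    z = cent[:, 2]
    ok = (z > z.min() + end_margin) & (z < z.max() - end_margin)
    cand = np.where(ok)[0]
    pick = rng.choice(cand, size=min(n_probes, len(cand)), replace=False)

    wall_sel = mesh.region_tags == "wall"
    wtets = mesh.tets[wall_sel][:, :4]
    wcent = mesh.nodes[wtets].mean(axis=1)
    from scipy.spatial import cKDTree

    tree = cKDTree(wcent)
    g, _ = _corner_gradients_for_location(mesh.nodes, wtets)

    counts = []
    for fi in pick:
        tri = mesh.nodes[ext[fi]]
        p = tri.mean(axis=0)
        n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        n = n / np.linalg.norm(n)
        # exterior facets are oriented outward: probe inward
        # march until leaving the wall region (max 10 mm)
        ts = np.linspace(0.05, 10.0, 300)
        pts = p[None, :] - ts[:, None] * n[None, :]
        _, idx = tree.query(pts, k=min(24, len(wtets)))
        ids = _locate_in_tets(mesh.nodes, wtets, g, pts, idx)
        ids = ids[ids >= 0]
        counts.append(len(np.unique(ids)) if len(ids) else 0)
    return np.asarray(counts)


def _corner_gradients_for_location(nodes, tets):
    p = [nodes[tets[:, i]] for i in range(4)]
    J = np.stack([p[1] - p[0], p[2] - p[0], p[3] - p[0]], axis=2)
    Jinv = np.linalg.inv(J)
    return Jinv, p[0]


def _locate_in_tets(nodes, tets, Jinv, pts, candidates):
    """Containing tet id per point (-1 if none) among KD-tree candidates."""
    p0 = nodes[tets[:, 0]]
    out = np.full(len(pts), -1, dtype=np.int64)
    for i, (pt, cand) in enumerate(zip(pts, candidates)):
        local = np.einsum("nij,nj->ni", Jinv[cand], pt - p0[cand])
        lam0 = 1.0 - local.sum(axis=1)
        inside = (local >= -1e-9).all(axis=1) & (lam0 >= -1e-9)
        hits = np.where(inside)[0]
        if len(hits):
            out[i] = cand[hits[0]]
    return out


def quality_report(mesh: TetMesh) -> dict:
    """Scaled-Jacobian and dihedral-angle quality summary plus counts."""
    t = mesh.tets[:, :4]
    p = [mesh.nodes[t[:, i]] for i in range(4)]
    e1, e2, e3 = p[1] - p[0], p[2] - p[0], p[3] - p[0]
    det = np.einsum("ij,ij->i", e1, np.cross(e2, e3))
    # scaled Jacobian: det over the product of the three edge norms at each
    # corner (min over corners), scaled so the regular tetrahedron scores 1
    corner_edges = [(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)]
    sj = np.full(len(t), np.inf)
    for ci, others in enumerate(corner_edges):
        prod = np.ones(len(t))
        for o in others:
            prod *= np.linalg.norm(p[o] - p[ci], axis=1)
        prod[prod == 0] = np.inf
        sj = np.minimum(sj, det / prod * np.sqrt(2.0))
    # dihedral angles over the 6 edges
    faces = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    fn = []
    for (i, j, k) in faces:
        n = np.cross(p[j] - p[i], p[k] - p[i])
        fn.append(n / np.linalg.norm(n, axis=1, keepdims=True))
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    dih = []
    for (i, j) in pairs:
        c = np.clip(np.abs(np.einsum("ij,ij->i", fn[i], fn[j])), 0, 1)
        dih.append(np.degrees(np.arccos(c)))
    dih = np.stack(dih)
    counts = {
        r: int((mesh.region_tags == r).sum()) for r in np.unique(mesh.region_tags)
    }
    return {
        "min_scaled_jacobian": float(sj.min()),
        "median_scaled_jacobian": float(np.median(sj)),
        "min_dihedral_deg": float(dih.min()),
        "max_dihedral_deg": float(180.0 - dih.min()),
        "n_nodes": int(mesh.n_nodes),
        "n_tets": int(len(mesh.tets)),
        "element_counts": counts,
        "node_counts": {
            r: int(len(np.unique(mesh.tets[mesh.region_tags == r].ravel())))
            for r in counts
        },
    }
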