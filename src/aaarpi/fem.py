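"""Linear-elasticity wall-stress analysis under internal pressure.

The imaged aneurysm geometry is the deformed, pressurized configuration, and
such a structure is statically determined: the stress field that balances
the blood pressure depends on geometry and load but only very weakly on the
material constants.  A single small-strain, linear solve on the imaged
geometry therefore recovers the wall stress without patient-specific
material data; the default constants below only anchor this insensitivity,
they are not tissue properties.

Three loading scenarios are supported:

* ``ilt_pressure`` — wall + thrombus meshed, pressure on the ILT luminal
  surface (the thrombus transmits the load to the wall);
* ``wall_pressure`` — wall + thrombus meshed and bonded, but the pressure is
  applied directly on the internal wall surface, bypassing the thrombus;
* ``no_ilt``       — wall only, pressure on the internal wall surface.

Elements are displacement-only linear (4-node) or quadratic (10-node)
tetrahedra; all translations are fixed on the end-cap node sets.  Maximum
principal stress is recovered at nodes by volume-weighted averaging of
element stress tensors followed by eigen-decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import SolverError
from .meshing import TET10_EDGES, TetMesh

__all__ = [
    "Material",
    "ScenarioSpec",
    "FemResult",
    "DEFAULT_MATERIALS",
    "MMHG_TO_MPA",
    "assemble_stiffness",
    "pressure_loads",
    "solve_scenario",
    "solve_scenarios",
    "excluded_peak_sigma1",
    "compare_scenarios",
]

MMHG_TO_MPA = 133.322e-6  # 1 mmHg in MPa


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic constants: E in MPa, Poisson ratio."""

    youngs_modulus: float
    poisson_ratio: float

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise SolverError("Young's modulus must be positive")
        if not (0 <= self.poisson_ratio < 0.5):
            raise SolverError("Poisson ratio must be in [0, 0.5)")

    def d_matrix(self) -> np.ndarray:
        """6x6 constitutive matrix (Voigt: xx, yy, zz, xy, yz, zx)."""
        E, nu = self.youngs_modulus, self.poisson_ratio
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.arange(3), np.arange(3)] += 2 * mu
        D[np.arange(3, 6), np.arange(3, 6)] = mu
        return D


# Wall ~20x stiffer than thrombus, both nearly incompressible; the stress
# result is insensitive to these by design.
DEFAULT_MATERIALS = {
    "wall": Material(1.0, 0.49),
    "ilt": Material(0.05, 0.49),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One loading scenario: which regions are meshed and where the pressure acts."""

    name: str  # "ilt_pressure" | "wall_pressure" | "no_ilt"
    include_ilt: bool
    load_surface: str  # "ilt_luminal" | "internal_wall"
    pressure: float  # MPa

    def __post_init__(self) -> None:
        if self.name not in ("ilt_pressure", "wall_pressure", "no_ilt"):
            raise SolverError(f"unknown scenario {self.name!r}")
        if self.name == "no_ilt" and (self.include_ilt or self.load_surface != "internal_wall"):
            raise SolverError("no_ilt scenario: no ILT, load on internal wall")
        if self.name == "ilt_pressure" and self.load_surface != "ilt_luminal":
            raise SolverError("ilt_pressure scenario loads the ILT luminal surface")
        if self.pressure < 0:
            raise SolverError("pressure must be >= 0")

    @classmethod
    def standard(cls, name: str, pressure_mpa: float) -> "ScenarioSpec":
        table = {
            "ilt_pressure": (True, "ilt_luminal"),
            "wall_pressure": (True, "internal_wall"),
            "no_ilt": (False, "internal_wall"),
        }
        inc, surf = table[name]
        return cls(name, inc, surf, pressure_mpa)


@dataclass
class FemResult:
    """Nodal solution fields of one scenario."""

    displacement: np.ndarray  # (n, 3) mm
    nodal_stress: np.ndarray  # (n, 6) Voigt, MPa (volume-averaged)
    nodal_sigma1: np.ndarray  # (n,) max principal stress, MPa
    wall_node_ids: np.ndarray  # nodes belonging to wall elements
    equilibrium_residual: float  # |sum reactions + sum loads| / |sum loads|


# ---------------------------------------------------------------------------
# element matrices

_GAUSS4_BARY = np.array(
    [
        [0.58541020, 0.13819660, 0.13819660, 0.13819660],
        [0.13819660, 0.58541020, 0.13819660, 0.13819660],
        [0.13819660, 0.13819660, 0.58541020, 0.13819660],
        [0.13819660, 0.13819660, 0.13819660, 0.58541020],
    ]
)


def _corner_gradients(nodes: np.ndarray, tets: np.ndarray):
    """Gradients of barycentric coordinates and 6x element volumes.

    Returns (grad (ne, 4, 3), vol (ne,)).
    """
    p = [nodes[tets[:, i]] for i in range(4)]
    J = np.stack([p[1] - p[0], p[2] - p[0], p[3] - p[0]], axis=2)  # (ne,3,3)
    det = np.linalg.det(J)
    if (det <= 0).any():
        raise SolverError(f"{int((det <= 0).sum())} inverted elements")
    Jinv = np.linalg.inv(J)  # Jinv[i, :] = grad of barycentric coord i+1
    g = np.empty((len(tets), 4, 3))
    g[:, 1:, :] = Jinv
    g[:, 0, :] = -Jinv.sum(axis=1)
    return g, det / 6.0


def _tet10_dN(bary: np.ndarray) -> np.ndarray:
    """dN/dlambda for the 10 quadratic shape functions at one barycentric
    point; shape (10, 4)."""
    lam = bary
    dN = np.zeros((10, 4))
    for i in range(4):
        dN[i, i] = 4 * lam[i] - 1
    for e, (a, b) in enumerate(TET10_EDGES):
        dN[4 + e, a] = 4 * lam[b]
        dN[4 + e, b] = 4 * lam[a]
    return dN


def _b_matrix(dndx: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices from shape gradients (ne, n_sh, 3) ->
    (ne, 6, 3*n_sh), Voigt order xx, yy, zz, xy, yz, zx (engineering shear)."""
    ne, nsh, _ = dndx.shape
    B = np.zeros((ne, 6, 3 * nsh))
    gx, gy, gz = dndx[:, :, 0], dndx[:, :, 1], dndx[:, :, 2]
    B[:, 0, 0::3] = gx
    B[:, 1, 1::3] = gy
    B[:, 2, 2::3] = gz
    B[:, 3, 0::3] = gy
    B[:, 3, 1::3] = gx
    B[:, 4, 1::3] = gz
    B[:, 4, 2::3] = gy
    B[:, 5, 0::3] = gz
    B[:, 5, 2::3] = gx
    return B


def _element_b_at(mesh: TetMesh, bary_points: np.ndarray):
    """B matrices per element per integration point and weights.

    Yields (B (ne, 6, 3*nsh), weight_volume (ne,)) per point.
    """
    g, vol = _corner_gradients(mesh.nodes, mesh.tets)
    nsh = mesh.tets.shape[1]
    for bp in bary_points:
        if nsh == 4:
            dndx = g  # constant
        else:
            dN = _tet10_dN(bp)  # (10, 4)
            dndx = np.einsum("sk,nkj->nsj", dN, g)
        yield _b_matrix(dndx), vol / len(bary_points)


def assemble_stiffness(
    mesh: TetMesh, materials: dict[str, Material] = DEFAULT_MATERIALS
) -> sp.csr_matrix:
    """Global stiffness matrix (3n x 3n), SPD up to 6 rigid-body modes.

    Linear tets use single-point integration (exact); quadratic tets the
    4-point Gauss rule (exact for straight-sided elements).
    """
    n = mesh.n_nodes
    nsh = mesh.tets.shape[1]
    ndof_e = 3 * nsh
    D = np.zeros((len(mesh.tets), 6, 6))
    for region, mat in materials.items():
        sel = mesh.region_tags == region
        D[sel] = mat.d_matrix()
    if not D.any():
        raise SolverError("no material assigned to any region present")
    if nsh == 4:
        for region, mat in materials.items():
            if mat.poisson_ratio >= 0.45 and (mesh.region_tags == region).any():
                warnings.warn(
                    "linear tetrahedra lock for nearly incompressible "
                    f"materials (nu={mat.poisson_ratio} in {region}); "
                    "prefer quadratic elements",
                    stacklevel=2,
                )

    edof = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(
        len(mesh.tets), ndof_e
    )
    bary = _GAUSS4_BARY if nsh == 10 else np.full((1, 4), 0.25)

    K = sp.csr_matrix((3 * n, 3 * n))
    chunk = 20000
    Ke = np.zeros((len(mesh.tets), ndof_e, ndof_e))
    for B, w in _element_b_at(mesh, bary):
        Ke += np.einsum("nip,nij,njq,n->npq", B, D, B, w, optimize=True)
    for s in range(0, len(mesh.tets), chunk):
        sl = slice(s, min(s + chunk, len(mesh.tets)))
        ed = edof[sl]
        rows = np.repeat(ed, ndof_e, axis=1).ravel()
        cols = np.tile(ed, (1, ndof_e)).ravel()
        K = K + sp.coo_matrix(
            (Ke[sl].ravel(), (rows, cols)), shape=(3 * n, 3 * n)
        ).tocsr()
    return K


def pressure_loads(mesh: TetMesh, surface_tag: str, pressure: float) -> np.ndarray:
    """Consistent nodal force vector for uniform pressure on a tagged surface.

    Facet sets are stored oriented so their normals point from the fluid side
    into the loaded solid; a positive pressure therefore pushes into the
    region.  For straight-sided quadratic facets the consistent load puts the
    whole force on the mid-edge nodes.
    """
    if surface_tag not in mesh.facet_sets:
        raise SolverError(f"no facet set {surface_tag!r} in mesh")
    f = np.zeros(3 * mesh.n_nodes)
    if pressure == 0:
        return f
    facets = mesh.facet_sets[surface_tag]
    tri = facets[:, :3]
    a, b, c = mesh.nodes[tri[:, 0]], mesh.nodes[tri[:, 1]], mesh.nodes[tri[:, 2]]
    nvec = 0.5 * np.cross(b - a, c - a)  # area-weighted normal
    if facets.shape[1] == 3:
        contrib = pressure * nvec / 3.0
        for k in range(3):
            np.add.at(f, 3 * facets[:, k], contrib[:, 0])
            np.add.at(f, 3 * facets[:, k] + 1, contrib[:, 1])
            np.add.at(f, 3 * facets[:, k] + 2, contrib[:, 2])
    else:
        contrib = pressure * nvec / 3.0
        for k in range(3, 6):  # mid-edge nodes carry the consistent load
            np.add.at(f, 3 * facets[:, k], contrib[:, 0])
            np.add.at(f, 3 * facets[:, k] + 1, contrib[:, 1])
            np.add.at(f, 3 * facets[:, k] + 2, contrib[:, 2])
    return f


def _element_stress(mesh: TetMesh, materials, u: np.ndarray):
    """Element stress tensors (Voigt) at the element centroid and volumes."""
    g, vol = _corner_gradients(mesh.nodes, mesh.tets)
    nsh = mesh.tets.shape[1]
    if nsh == 4:
        dndx = g
    else:
        dN = _tet10_dN(np.full(4, 0.25))
        dndx = np.einsum("sk,nkj->nsj", dN, g)
    B = _b_matrix(dndx)
    edof = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(
        len(mesh.tets), 3 * nsh
    )
    ue = u[edof]
    eps = np.einsum("nij,nj->ni", B, ue)
    D = np.zeros((len(mesh.tets), 6, 6))
    for region, mat in materials.items():
        sel = mesh.region_tags == region
        D[sel] = mat.d_matrix()
    sig = np.einsum("nij,nj->ni", D, eps)
    return sig, vol


def _nodal_sigma(mesh: TetMesh, sig: np.ndarray, vol: np.ndarray, region: str = "wall"):
    """Volume-weighted nodal average of element stress, then max principal.

    Averaging is restricted to one region's elements: wall stress at the
    wall/thrombus interface must not be diluted by the much softer thrombus
    elements sharing those nodes.
    """
    n = mesh.n_nodes
    sel = mesh.region_tags == region
    tets, sig, vol = mesh.tets[sel], sig[sel], vol[sel]
    acc = np.zeros((n, 6))
    wsum = np.zeros(n)
    for k in range(tets.shape[1]):
        idx = tets[:, k]
        np.add.at(acc, idx, sig * vol[:, None])
        np.add.at(wsum, idx, vol)
    wsum[wsum == 0] = 1.0
    nodal = acc / wsum[:, None]
    T = np.empty((n, 3, 3))
    T[:, 0, 0], T[:, 1, 1], T[:, 2, 2] = nodal[:, 0], nodal[:, 1], nodal[:, 2]
    T[:, 0, 1] = T[:, 1, 0] = nodal[:, 3]
    T[:, 1, 2] = T[:, 2, 1] = nodal[:, 4]
    T[:, 0, 2] = T[:, 2, 0] = nodal[:, 5]
    sigma1 = np.linalg.eigvalsh(T)[:, -1]
    return nodal, sigma1


def solve_scenarios(
    mesh: TetMesh,
    scenarios: list[ScenarioSpec],
    materials: dict[str, Material] = DEFAULT_MATERIALS,
    fixed_sets: tuple[str, ...] = ("caps_top", "caps_bottom"),
) -> dict[str, FemResult]:
    """Solve several load cases sharing one mesh with one factorization.

    The ``ilt_pressure`` and ``wall_pressure`` scenarios differ only in the
    loaded surface, so the stiffness factorization (the dominant cost) is
    reused across them.  The mesh must contain exactly the regions the
    scenarios include.
    """
    if not scenarios:
        raise SolverError("no scenarios given")
    present = set(np.unique(mesh.region_tags))
    for sc in scenarios:
        if sc.include_ilt and "ilt" not in present:
            raise SolverError(f"{sc.name}: mesh has no ILT region")
        if not sc.include_ilt and "ilt" in present:
            raise SolverError(f"{sc.name}: mesh contains an ILT region")
    mats = {r: materials[r] for r in present}
    K = assemble_stiffness(mesh, mats)
    fixed_nodes = np.unique(
        np.concatenate([mesh.node_sets[s] for s in fixed_sets])
    )
    fixed_dofs = (3 * fixed_nodes[:, None] + np.arange(3)[None, :]).ravel()
    n = K.shape[0]
    free = np.ones(n, dtype=bool)
    free[fixed_dofs] = False
    Kff = K[free][:, free].tocsc()
    try:
        lu = spla.splu(Kff)
    except RuntimeError as e:  # pragma: no cover - singular systems
        raise SolverError(f"stiffness factorization failed: {e}") from e

    out: dict[str, FemResult] = {}
    for sc in scenarios:
        f = pressure_loads(mesh, sc.load_surface, sc.pressure)
        uf = lu.solve(f[free])
        if not np.isfinite(uf).all():
            raise SolverError(f"{sc.name}: non-finite displacements")
        u = np.zeros(n)
        u[free] = uf
        # equilibrium: reactions at the fixed DOF balance the applied load;
        # solver error shows up through the free-DOF residual of K u - f
        r = (K @ u - f).reshape(-1, 3)
        reactions = r[fixed_nodes].sum(axis=0)
        free_resid = np.delete(r, fixed_nodes, axis=0).sum(axis=0)
        total_load = f.reshape(-1, 3).sum(axis=0)
        denom = np.linalg.norm(f.reshape(-1, 3), axis=1).sum()
        resid = (
            float(np.linalg.norm(reactions + free_resid + total_load) / denom)
            if denom > 0
            else 0.0
        )
        sig, vol = _element_stress(mesh, mats, u)
        nodal, sigma1 = _nodal_sigma(mesh, sig, vol)
        out[sc.name] = FemResult(
            displacement=u.reshape(-1, 3),
            nodal_stress=nodal,
            nodal_sigma1=sigma1,
            wall_node_ids=mesh.wall_nodes(),
            equilibrium_residual=resid,
        )
    return out


def solve_scenario(
    mesh: TetMesh,
    scenario: ScenarioSpec,
    materials: dict[str, Material] = DEFAULT_MATERIALS,
    fixed_sets: tuple[str, ...] = ("caps_top", "caps_bottom"),
) -> FemResult:
    """Solve one loading scenario on a mesh built for it.

    The mesh must contain only the regions the scenario includes (build the
    ``no_ilt`` mesh with ``include_ilt=False``).  All translations of the
    end-cap node sets are fixed.
    """
    return solve_scenarios(mesh, [scenario], materials, fixed_sets)[scenario.name]


def excluded_peak_sigma1(
    mesh: TetMesh, result: FemResult, exclusion_mask: np.ndarray
) -> float:
    """Peak nodal maximum-principal stress on wall nodes outside the mask."""
    keep = np.ones(mesh.n_nodes, dtype=bool)
    keep[exclusion_mask] = False
    wall = np.zeros(mesh.n_nodes, dtype=bool)
    wall[result.wall_node_ids] = True
    sel = wall & keep
    if not sel.any():
        raise SolverError("exclusion mask removes every wall node")
    return float(result.nodal_sigma1[sel].max())


def compare_scenarios(
    peaks: dict[str, float],
) -> dict:
    """Pairwise relative differences and the no-ILT amplification ratio.

    ``peaks`` maps scenario name to excluded-peak wall stress (MPa).
    Relative differences are normalized by the larger of each pair.
    """
    out: dict = {"peaks": dict(peaks)}
    names = sorted(peaks)
    diffs = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            hi = max(peaks[a], peaks[b])
            diffs[f"{a}_vs_{b}"] = (
                abs(peaks[a] - peaks[b]) / hi if hi > 0 else 0.0
            )
    out["relative_differences"] = diffs
    if "no_ilt" in peaks and "ilt_pressure" in peaks and peaks["ilt_pressure"] > 0:
        out["no_ilt_over_ilt_pressure"] = peaks["no_ilt"] / peaks["ilt_pressure"]
    return out
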