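"""FEM verification: patch/oracle tests, Lamé benchmark, load identities."""

import numpy as np
import pytest

from aaarpi.errors import SolverError
from aaarpi.fem import (
    Material,
    ScenarioSpec,
    assemble_stiffness,
    pressure_loads,
    solve_scenario,
)
from aaarpi.geometry import (
    AaaGeometry,
    build_end_caps,
    build_size_field,
    offset_internal_wall,
)
from aaarpi.meshing import TetMesh, mesh_regions
from aaarpi.primitives import sphere_surface, tube_surface


def single_tet_mesh(order=1):
    nodes = np.array(
        [[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0], [0.0, 0, 1]]
    )
    tets = np.array([[0, 1, 2, 3]])
    m = TetMesh(nodes, tets, np.array(["wall"]), {}, {})
    if order == 2:
        from aaarpi.meshing import _elevate_order

        m = _elevate_order(m)
    return m


def sympy_reference_stiffness(nodes, E, nu):
    """Independent oracle: K_ij = d2U/du_i du_j with U = 1/2 int eps:C:eps,
    built from symbolic linear shape functions on one tetrahedron."""
    import sympy as sp

    x, y, z = sp.symbols("x y z")
    # linear shape functions from the Vandermonde system
    A = sp.Matrix([[1, *nodes[i]] for i in range(4)])
    coeffs = A.inv()
    N = [coeffs[0, i] + coeffs[1, i] * x + coeffs[2, i] * y + coeffs[3, i] * z for i in range(4)]
    u = sp.symbols("u0:12")
    ux = sum(N[i] * u[3 * i] for i in range(4))
    uy = sum(N[i] * u[3 * i + 1] for i in range(4))
    uz = sum(N[i] * u[3 * i + 2] for i in range(4))
    ex, ey, ez = sp.diff(ux, x), sp.diff(uy, y), sp.diff(uz, z)
    gxy = sp.diff(ux, y) + sp.diff(uy, x)
    gyz = sp.diff(uy, z) + sp.diff(uz, y)
    gzx = sp.diff(ux, z) + sp.diff(uz, x)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    tr = ex + ey + ez
    W = (
        sp.Rational(1, 2) * lam * tr**2
        + mu * (ex**2 + ey**2 + ez**2)
        + sp.Rational(1, 2) * mu * (gxy**2 + gyz**2 + gzx**2)
    )
    vol = abs(A.det()) / 6
    K = sp.zeros(12, 12)
    for i in range(12):
        for j in range(12):
            K[i, j] = sp.diff(W, u[i], u[j]) * vol
    return np.array(K, dtype=float)


class TestStiffness:
    def test_single_tet_matches_symbolic_oracle(self):
        m = single_tet_mesh()
        E, nu = 2.0, 0.3
        K = assemble_stiffness(m, {"wall": Material(E, nu)}).toarray()
        Kref = sympy_reference_stiffness(m.nodes, E, nu)
        assert np.allclose(K, Kref, atol=1e-12)

    @pytest.mark.parametrize("order", [1, 2])
    def test_symmetry_and_rigid_modes(self, order):
        m = single_tet_mesh(order)
        K = assemble_stiffness(m, {"wall": Material(1.0, 0.3)}).toarray()
        assert np.allclose(K, K.T, atol=1e-12)
        # translations and infinitesimal rotations are zero-energy
        n = m.n_nodes
        modes = []
        for d in range(3):
            v = np.zeros((n, 3))
            v[:, d] = 1.0
            modes.append(v.ravel())
        x = m.nodes
        modes.append(np.column_stack([-x[:, 1], x[:, 0], np.zeros(n)]).ravel())
        modes.append(np.column_stack([np.zeros(n), -x[:, 2], x[:, 1]]).ravel())
        modes.append(np.column_stack([x[:, 2], np.zeros(n), -x[:, 0]]).ravel())
        for v in modes:
            assert np.abs(K @ v).max() < 1e-10
        w = np.linalg.eigvalsh(K)
        assert (w > -1e-10).all()  # positive semidefinite
        assert (np.abs(w) < 1e-10).sum() == 6  # exactly six zero modes

    def test_patch_constant_strain(self):
        # constant-strain displacement reproduces the exact uniform stress
        from aaarpi.fem import _element_stress

        m = single_tet_mesh(2)
        mats = {"wall": Material(2.0, 0.3)}
        u = np.zeros((m.n_nodes, 3))
        u[:, 0] = 0.1 * m.nodes[:, 0]
        sig, _ = _element_stress(m, mats, u.ravel())
        lam = 2.0 * 0.3 / (1.3 * 0.4)
        mu = 1.0 / 1.3
        assert sig[0, 0] == pytest.approx(lam * 0.1 + 2 * mu * 0.1, rel=1e-12)
        assert sig[0, 1] == pytest.approx(lam * 0.1, rel=1e-12)
        assert np.abs(sig[0, 3:]).max() < 1e-14

    def test_locking_warning_for_linear_incompressible(self):
        m = single_tet_mesh(1)
        with pytest.warns(UserWarning, match="lock"):
            assemble_stiffness(m, {"wall": Material(1.0, 0.49)})


class TestPressureLoads:
    def test_zero_pressure_zero_vector(self):
        m = single_tet_mesh()
        m.facet_sets["side"] = np.array([[0, 1, 2]])
        assert not pressure_loads(m, "side", 0.0).any()

    def test_unit_square_total_force(self):
        nodes = np.array(
            [[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0.5, 0.5, 1]]
        )
        tets = np.array([[0, 1, 2, 4], [0, 2, 3, 4]])
        m = TetMesh(nodes, tets, np.array(["wall", "wall"]), {}, {})
        m.facet_sets["base"] = np.array([[0, 1, 2], [0, 2, 3]])
        f = pressure_loads(m, "base", 2.0).reshape(-1, 3)
        total = f.sum(axis=0)
        # area 1, pressure 2, facet normal +z for this winding
        assert np.allclose(total, [0, 0, 2.0], atol=1e-12)

    def test_closed_sphere_nets_zero(self):
        s = sphere_surface(10.0, 3)
        nodes = np.vstack([s.vertices, [[0, 0, 0]]])
        c = len(nodes) - 1
        tets = np.column_stack(
            [s.triangles, np.full(len(s.triangles), c)]
        )
        m = TetMesh(nodes, tets, np.array(["wall"] * len(tets)), {}, {})
        m.facet_sets["shell"] = s.triangles
        f = pressure_loads(m, "shell", 1.0).reshape(-1, 3)
        total = f.sum(axis=0)
        area = s.area()
        assert np.linalg.norm(total) / area < 1e-10

    def test_missing_tag_rejected(self):
        with pytest.raises(SolverError):
            pressure_loads(single_tet_mesh(), "nope", 1.0)


@pytest.fixture(scope="module")
def lame_cylinder():
    """Quadratic mesh of a thick-walled tube, solved under internal pressure."""
    R, L, th, p = 25.0, 100.0, 1.5, 0.016
    ext = tube_surface(R, L, n_circ=36, n_axial=18)
    thf = np.full(ext.n_vertices, th)
    internal = offset_internal_wall(ext, thf)
    geom = AaaGeometry(ext, internal, None, {}, thf, np.zeros(ext.n_vertices))
    geom.caps = build_end_caps(geom)
    sf = build_size_field(geom, n_layers=2)
    mesh = mesh_regions(geom, sf, order=2, include_ilt=False)
    res = solve_scenario(mesh, ScenarioSpec.standard("no_ilt", p))
    return mesh, res, (R, L, th, p)


class TestSolve:
    def test_lame_hoop_stress_within_5_percent(self, lame_cylinder):
        mesh, res, (R, L, th, p) = lame_cylinder
        a, b = R - th, R
        lame = p * (a * a + b * b) / (b * b - a * a)
        inner = mesh.node_sets["internal_wall"]
        mid = inner[np.abs(mesh.nodes[inner, 2] - L / 2) < 8]
        s1 = res.nodal_sigma1[mid]
        assert s1.mean() == pytest.approx(lame, rel=0.05)

    def test_equilibrium_residual(self, lame_cylinder):
        _, res, _ = lame_cylinder
        assert res.equilibrium_residual < 1e-6

    def test_stress_invariant_under_stiffness_scaling(self, lame_cylinder):
        mesh, res, (_, _, _, p) = lame_cylinder
        stiff = solve_scenario(
            mesh,
            ScenarioSpec.standard("no_ilt", p),
            {"wall": Material(10.0, 0.49)},
        )
        ref = np.abs(res.nodal_sigma1).max()
        assert np.abs(stiff.nodal_sigma1 - res.nodal_sigma1).max() < 1e-8 * ref

    def test_zero_pressure_zero_stress(self, lame_cylinder):
        mesh, _, _ = lame_cylinder
        res0 = solve_scenario(mesh, ScenarioSpec.standard("no_ilt", 0.0))
        assert np.abs(res0.nodal_sigma1).max() < 1e-14
        assert np.abs(res0.displacement).max() < 1e-14


def test_compare_scenarios_record():
    from aaarpi.fem import compare_scenarios

    cmp_eq = compare_scenarios({"ilt_pressure": 0.2, "wall_pressure": 0.2})
    assert cmp_eq["relative_differences"]["ilt_pressure_vs_wall_pressure"] == 0.0
    cmp2 = compare_scenarios(
        {"ilt_pressure": 0.1, "wall_pressure": 0.102, "no_ilt": 0.3}
    )
    assert cmp2["no_ilt_over_ilt_pressure"] == pytest.approx(3.0)
    assert cmp2["relative_differences"]["ilt_pressure_vs_wall_pressure"] == (
        pytest.approx(0.002 / 0.102)
    )


class TestScenarioSpec:
    def test_invalid_combinations_rejected(self):
        with pytest.raises(SolverError):
            ScenarioSpec("no_ilt", True, "internal_wall", 0.016)
        with pytest.raises(SolverError):
            ScenarioSpec("ilt_pressure", True, "internal_wall", 0.016)
        with pytest.raises(SolverError):
            ScenarioSpec("bogus", False, "internal_wall", 0.016)

    def test_mesh_scenario_mismatch_rejected(self, lame_cylinder):
        mesh, _, _ = lame_cylinder  # wall-only mesh
        with pytest.raises(SolverError):
            solve_scenario(mesh, ScenarioSpec.standard("ilt_pressure", 0.016))
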