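"""Tetrahedral meshing: conformity, tagging, quality, layer counts."""

import numpy as np
import pytest

from aaarpi.errors import MeshError
from aaarpi.geometry import region_shell
from aaarpi.meshing import (
    TetMesh,
    count_wall_layers,
    extrude_shell,
    mesh_regions,
    quality_report,
)
from aaarpi.surface import TriSurface, enclosed_volume


def unit_cube_mesh(n=2):
    """Structured unit cube from extruded sheets of a gridded square."""
    xs, ys = np.meshgrid(np.linspace(0, 1, n + 1), np.linspace(0, 1, n + 1))
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros((n + 1) ** 2)])
    tris = []
    for i in range(n):
        for j in range(n):
            a = (n + 1) * i + j
            tris.append((a, a + n + 1, a + 1))
            tris.append((a + 1, a + n + 1, a + n + 2))
    surf = TriSurface(verts, np.asarray(tris))
    sheets = [verts + [0, 0, k / n] for k in range(n + 1)]
    nodes, tets = extrude_shell(surf, sheets)
    a, b, c, d = (nodes[tets[:, i]] for i in range(4))
    vol6 = np.einsum("ij,ij->i", b - a, np.cross(c - a, d - a))
    tets[vol6 < 0] = tets[vol6 < 0][:, [0, 2, 1, 3]]
    return TetMesh(nodes, tets, np.array(["wall"] * len(tets)), {}, {})


class TestExtrusion:
    def test_unit_cube_volume_conserved(self):
        m = unit_cube_mesh(4)
        assert (m.volumes() > 0).all()
        assert m.volumes().sum() == pytest.approx(1.0, rel=1e-9)

    def test_prism_split_conforms_between_neighbors(self):
        # every interior facet must be shared by exactly two tets
        m = unit_cube_mesh(3)
        faces = {}
        for tet in m.tets:
            for f in ([0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]):
                key = tuple(sorted(tet[f]))
                faces[key] = faces.get(key, 0) + 1
        assert set(faces.values()) <= {1, 2}


def test_quality_report_regular_tet():
    """A regular tetrahedron scores scaled Jacobian 1 by construction."""
    a = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    )
    m = TetMesh(a, np.array([[0, 1, 2, 3]]), np.array(["wall"]), {}, {})
    if m.volumes()[0] < 0:
        m.tets = m.tets[:, [0, 2, 1, 3]]
    q = quality_report(m)
    assert q["min_scaled_jacobian"] == pytest.approx(1.0)
    assert q["min_dihedral_deg"] == pytest.approx(70.5288, abs=0.01)


class TestPhantomMesh:
    def test_region_volumes_match_shells(self, fine_geometry, fine_mesh1):
        geom, _ = fine_geometry
        for region in ("wall", "ilt"):
            shell = enclosed_volume(region_shell(geom, region))
            assert abs(fine_mesh1.region_volume(region) - shell) / shell < 0.02

    def test_conforming_interface_no_duplicate_nodes(self, fine_mesh1):
        from scipy.spatial import cKDTree

        wall = np.unique(fine_mesh1.tets[fine_mesh1.region_tags == "wall"].ravel())
        ilt = np.unique(fine_mesh1.tets[fine_mesh1.region_tags == "ilt"].ravel())
        shared = np.intersect1d(wall, ilt)
        assert len(shared) > 0  # interface nodes are literally shared
        pairs = cKDTree(fine_mesh1.nodes).query_pairs(1e-9)
        assert len(pairs) == 0  # and no duplicated coordinates anywhere

    def test_all_volumes_positive(self, fine_mesh1):
        assert (fine_mesh1.volumes() > 1e-12).all()

    def test_quality_gate(self, fine_mesh1):
        q = quality_report(fine_mesh1)
        assert q["min_scaled_jacobian"] > 0.05

    def test_facet_tags_lie_on_their_surfaces(self, fine_geometry, fine_mesh1):
        geom, _ = fine_geometry
        from aaarpi.surface import NearestPointLocator

        for tag, surf in (
            ("exterior_wall", geom.external_wall),
            ("internal_wall", geom.internal_wall),
        ):
            tris = fine_mesh1.facet_sets[tag][:, :3]
            cent = fine_mesh1.nodes[tris].mean(axis=1)
            _, d = NearestPointLocator(surf).query(cent[::5])
            assert np.percentile(d, 95) < 0.5

    def test_two_layers_span_wall(self, fine_mesh1):
        counts = count_wall_layers(fine_mesh1, n_probes=50)
        assert counts.min() >= 2

    def test_counts_consistent(self, fine_mesh1):
        q = quality_report(fine_mesh1)
        assert q["n_tets"] == len(fine_mesh1.tets)
        assert sum(q["element_counts"].values()) == len(fine_mesh1.tets)

    def test_order2_adds_midside_nodes(self, fine_geometry):
        geom, sf = fine_geometry
        m2 = mesh_regions(geom, sf, order=2)
        assert m2.tets.shape[1] == 10
        # mid-edge nodes are midpoints of their corner pairs
        from aaarpi.meshing import TET10_EDGES

        tet = m2.tets[123]
        for e, (a, b) in enumerate(TET10_EDGES):
            mid = 0.5 * (m2.nodes[tet[a]] + m2.nodes[tet[b]])
            assert np.allclose(m2.nodes[tet[4 + e]], mid)
        # facets become 6-node
        assert m2.facet_sets["exterior_wall"].shape[1] == 6

    def test_refined_size_field_increases_elements_keeps_quality(
        self, fine_geometry, fine_mesh1
    ):
        geom, sf = fine_geometry
        import dataclasses

        sf2 = dataclasses.replace(
            sf, sizes=0.5 * sf.sizes, n_layers=2 * sf.n_layers
        )
        m2 = mesh_regions(geom, sf2, order=1)
        assert len(m2.tets) > len(fine_mesh1.tets)
        assert quality_report(m2)["min_scaled_jacobian"] > 0.05

    def test_non_watertight_input_rejected(self, fine_geometry):
        geom, sf = fine_geometry
        import copy

        broken = copy.copy(geom)
        broken.caps = {k: v for k, v in geom.caps.items() if k[1] != "distal"}
        with pytest.raises(MeshError):
            mesh_regions(broken, sf)

    def test_bad_order_rejected(self, fine_geometry):
        geom, sf = fine_geometry
        with pytest.raises(MeshError):
            mesh_regions(geom, sf, order=3)
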