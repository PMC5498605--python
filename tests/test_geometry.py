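"""Geometry stage: subtraction, separation, offsets, ILT rules, size field."""

import numpy as np
import pytest

from aaarpi.errors import GeometryError, SpecError
from aaarpi.geometry import (
    build_end_caps,
    build_size_field,
    compute_ilt_thickness,
    enforce_min_ilt_thickness,
    offset_internal_wall,
    region_shell,
    separate_surfaces,
    subtract_lumen,
)
from aaarpi.labelmap import LabelMapVolume
from aaarpi.phantom import PhantomSpec, generate_phantom
from aaarpi.primitives import sphere_surface, tube_surface
from aaarpi.surface import TriSurface, enclosed_volume, is_closed, NearestPointLocator


class TestSubtractLumen:
    def _maps(self):
        vox = np.zeros((20, 20, 10), dtype=np.uint8)
        vox[4:16, 4:16, :] = 1
        aaa = LabelMapVolume(vox, (1, 1, 2))
        lum = np.zeros_like(vox)
        lum[8:12, 8:12, :] = 1
        return aaa, LabelMapVolume(lum, (1, 1, 2))

    def test_empty_lumen_returns_aaa(self):
        aaa, _ = self._maps()
        empty = LabelMapVolume(np.zeros_like(aaa.voxels), aaa.spacing)
        out = subtract_lumen(aaa, empty)
        assert np.array_equal(out.voxels, aaa.voxels)

    def test_annular_result_per_slice(self):
        aaa, lum = self._maps()
        out = subtract_lumen(aaa, lum)
        for k in range(out.voxels.shape[2]):
            sl = out.voxels[:, :, k]
            assert sl.sum() == 12 * 12 - 4 * 4  # ring area per slice

    def test_protruding_lumen_clipped_first(self):
        aaa, lum = self._maps()
        lum.voxels[0:2, 0:2, :] = 1  # outside the AAA
        out = subtract_lumen(aaa, lum)
        # protruding voxels do not appear in the result as holes
        assert out.voxels[0:2, 0:2, :].sum() == 0
        assert out.voxels[4:8, 4:8, :].all()

    def test_total_cover_rejected(self):
        aaa, _ = self._maps()
        with pytest.raises(SpecError):
            subtract_lumen(aaa, aaa)


class TestSeparateSurfaces:
    def test_sphere_in_sphere(self):
        outer = sphere_surface(20.0, 3)
        inner = sphere_surface(8.0, 2)
        both = TriSurface(
            np.vstack([outer.vertices, inner.vertices]),
            np.vstack([outer.triangles, inner.triangles[:, ::-1] + outer.n_vertices]),
        )
        ext, lum = separate_surfaces(both)
        assert enclosed_volume(ext) > enclosed_volume(lum) > 0
        assert ext.n_vertices == outer.n_vertices

    def test_single_component_no_ilt(self):
        ext, lum = separate_surfaces(sphere_surface(15.0, 3))
        assert lum is None
        assert enclosed_volume(ext) > 0

    def test_three_components_rejected(self):
        parts = [sphere_surface(20.0, 2), sphere_surface(8.0, 2), sphere_surface(3.0, 2)]
        vs, fs, off = [], [], 0
        for p in parts:
            vs.append(p.vertices)
            fs.append(p.triangles + off)
            off += p.n_vertices
        with pytest.raises(GeometryError):
            separate_surfaces(TriSurface(np.vstack(vs), np.vstack(fs)))


class TestOffsetInternalWall:
    def test_cylinder_inner_radius(self):
        tube = tube_surface(25.0, 100.0, n_circ=96, n_axial=40)
        inner = offset_internal_wall(tube, np.full(tube.n_vertices, 1.5))
        mid = np.abs(inner.vertices[:, 2] - 50.0) < 10
        r = np.hypot(inner.vertices[mid, 0], inner.vertices[mid, 1])
        assert np.allclose(r, 23.5, rtol=0.01)

    def test_plane_patch_exact_distance(self):
        # flat grid in the xy plane, offset along -z by construction
        xs, ys = np.meshgrid(np.arange(5.0), np.arange(5.0))
        verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(25)])
        tris = []
        for i in range(4):
            for j in range(4):
                a = 5 * i + j
                tris.append((a, a + 5, a + 1))
                tris.append((a + 1, a + 5, a + 6))
        patch = TriSurface(verts, np.asarray(tris))
        t = 0.7
        out = offset_internal_wall(patch, np.full(25, t))
        d = np.linalg.norm(out.vertices - patch.vertices, axis=1)
        assert np.allclose(d, t, atol=1e-12)

    def test_sphere_becomes_smaller_sphere(self):
        s = sphere_surface(20.0, 3)
        out = offset_internal_wall(s, np.full(s.n_vertices, 2.0))
        r = np.linalg.norm(out.vertices - out.vertices.mean(axis=0), axis=1)
        assert np.allclose(r, 18.0, rtol=0.005)

    def test_excessive_offset_errors(self):
        s = sphere_surface(5.0, 2)
        with pytest.raises(GeometryError):
            offset_internal_wall(s, np.full(s.n_vertices, 6.0))

    def test_nonpositive_thickness_rejected(self):
        s = sphere_surface(5.0, 1)
        with pytest.raises(GeometryError):
            offset_internal_wall(s, np.zeros(s.n_vertices))


class TestMinIltThickness:
    def test_compliant_surfaces_unchanged(self):
        wall = tube_surface(20.0, 60.0, n_circ=48, n_axial=24)
        lum = tube_surface(10.0, 60.0, n_circ=48, n_axial=24)
        out = enforce_min_ilt_thickness(wall, lum, 1.0)
        assert np.array_equal(out.vertices, lum.vertices)

    def test_thin_gap_enforced_to_minimum(self):
        wall = tube_surface(10.0, 60.0, n_circ=64, n_axial=30)
        lum = tube_surface(9.7, 60.0, n_circ=64, n_axial=30)  # 0.3 mm gap
        out = enforce_min_ilt_thickness(wall, lum, 1.0)
        d = compute_ilt_thickness(wall, out)
        assert d.min() >= 1.0 - 0.02
        # moved inward, not outward
        r = np.hypot(out.vertices[:, 0], out.vertices[:, 1])
        assert r.max() <= 9.7 + 1e-9

    def test_partial_violation_moves_only_violators(self):
        wall = tube_surface(10.0, 60.0, n_circ=48, n_axial=24)
        lum = tube_surface(8.0, 60.0, n_circ=48, n_axial=24)
        # push one band of the lumen close to the wall
        sel = np.abs(lum.vertices[:, 2] - 30.0) < 5
        v = lum.vertices.copy()
        r = np.hypot(v[sel, 0], v[sel, 1])
        v[sel, :2] *= (9.6 / r)[:, None]
        lum2 = TriSurface(v, lum.triangles)
        out = enforce_min_ilt_thickness(wall, lum2, 1.0)
        far = np.abs(lum2.vertices[:, 2] - 30.0) > 10
        assert np.allclose(out.vertices[far], lum2.vertices[far])

    def test_lumen_too_small_errors(self):
        wall = tube_surface(3.0, 30.0, n_circ=32, n_axial=12)
        lum = tube_surface(2.5, 30.0, n_circ=32, n_axial=12)
        with pytest.raises(GeometryError):
            enforce_min_ilt_thickness(wall, lum, 5.0)


class TestIltThickness:
    def test_no_ilt_zero_field(self):
        wall = tube_surface(10.0, 30.0, n_circ=24, n_axial=10)
        assert np.all(compute_ilt_thickness(wall, None) == 0)

    def test_concentric_cylinders(self):
        wall = tube_surface(23.5, 80.0, n_circ=96, n_axial=40)
        lum = tube_surface(9.0, 80.0, n_circ=96, n_axial=40)
        d = compute_ilt_thickness(wall, lum)
        mid = np.abs(wall.vertices[:, 2] - 40.0) < 10
        assert d[mid] == pytest.approx(14.5, rel=0.01)

    def test_phantom_truth_recovered(self, small_geometry, small_phantom):
        geom, _ = small_geometry
        _, _, truth = small_phantom
        voxel_diag = np.linalg.norm([0.625, 0.625, 2.0])
        assert abs(geom.ilt_thickness.max() - truth.max_ilt_thickness) < voxel_diag


class TestSizeField:
    def test_near_wall_size_thickness_over_layers(self, small_geometry):
        geom, _ = small_geometry
        sf = build_size_field(geom, n_layers=2)
        probe = 0.5 * (geom.external_wall.vertices + geom.internal_wall.vertices)
        sizes = sf.sample(probe)
        assert np.median(sizes) == pytest.approx(0.75, rel=0.05)

    def test_one_layer_full_thickness(self, small_geometry):
        geom, _ = small_geometry
        sf = build_size_field(geom, n_layers=1)
        probe = 0.5 * (geom.external_wall.vertices + geom.internal_wall.vertices)
        assert np.median(sf.sample(probe)) == pytest.approx(1.5, rel=0.05)

    def test_ilt_mid_sizes_exceed_boundary_sizes(self, small_geometry):
        geom, _ = small_geometry
        sf = build_size_field(geom, n_layers=2, ilt_interior_growth=3.0)
        loc = NearestPointLocator(geom.ilt_luminal)
        target, _ = loc.query(geom.internal_wall.vertices)
        thick = np.linalg.norm(target - geom.internal_wall.vertices, axis=1)
        sel = thick > 8.0
        mid = 0.5 * (geom.internal_wall.vertices[sel] + target[sel])
        near_wall = geom.internal_wall.vertices[sel] + 0.1 * (target[sel] - geom.internal_wall.vertices[sel])
        assert sf.sample(mid).mean() > sf.sample(near_wall).mean()

    def test_positive_everywhere(self, small_geometry):
        geom, _ = small_geometry
        sf = build_size_field(geom)
        assert (sf.sizes > 0).all()


class TestEndCapsAndShells:
    def test_wall_shell_watertight(self, small_geometry):
        geom, _ = small_geometry
        sh = region_shell(geom, "wall")
        assert is_closed(sh)
        assert enclosed_volume(sh) > 0

    def test_ilt_shell_watertight(self, small_geometry):
        geom, _ = small_geometry
        sh = region_shell(geom, "ilt")
        assert is_closed(sh)
        assert enclosed_volume(sh) > 0

    def test_wall_volume_close_to_analytic(self, small_geometry):
        from conftest import SMALL_SPEC

        geom, _ = small_geometry
        vol = enclosed_volume(region_shell(geom, "wall"))
        z = np.linspace(0, SMALL_SPEC.total_length, 4001)
        r = SMALL_SPEC.outer_radius(z)
        ref = np.trapezoid(np.pi * (r**2 - (r - 1.5) ** 2), z)
        assert abs(vol - ref) / ref < 0.05

    def test_no_ilt_case_only_wall_caps(self):
        spec = PhantomSpec(
            neck_radius=11.0,
            max_radius=16.0,
            bulge_center_z=40.0,
            bulge_halfwidth=15.0,
            total_length=80.0,
            lumen_radius=9.0,
            voxel_spacing=(1.0, 1.0, 2.0),
        )
        aaa, _, _ = generate_phantom(spec)
        from aaarpi.geometry import build_geometry

        geom, _ = build_geometry(aaa, None, lambda s: 1.5, target_edge=4.0)
        assert geom.ilt_luminal is None
        assert set(r for r, _ in geom.caps) == {"wall"}
        assert np.all(geom.ilt_thickness == 0)

    def test_cap_normals_outward_axially(self, small_geometry):
        geom, _ = small_geometry
        for (region, end), cap in geom.caps.items():
            v, t = cap.vertices, cap.triangles
            n = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]]).sum(axis=0)
            sign = -1.0 if end == "proximal" else 1.0
            assert n[2] * sign > 0
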