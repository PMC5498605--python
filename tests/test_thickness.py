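"""Thickness annotations, Voronoi-like assignment, field smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aaarpi.errors import SpecError
from aaarpi.primitives import sphere_surface
from aaarpi.thickness import (
    ThicknessMeasurement,
    assign_nearest,
    load_thickness_annotations,
    smooth_field,
    thickness_field,
)


def _write_csv(path, rows):
    lines = ["x,y,z,thickness_mm"] + [",".join(str(v) for v in r) for r in rows]
    path.write_text("\n".join(lines) + "\n")


class TestLoad:
    def test_single_file_single_value_constant_mode(self, tmp_path):
        f = tmp_path / "a.csv"
        _write_csv(f, [(0, 0, 0, 1.5)])
        ms = load_thickness_annotations([f])
        assert len(ms) == 1 and ms[0].thickness == 1.5
        surf = sphere_surface(10.0, 2)
        field = thickness_field(surf, ms)
        assert np.all(field == 1.5)

    def test_empty_list_rejected(self):
        with pytest.raises(SpecError):
            load_thickness_annotations([])

    def test_two_files_two_measurements(self, tmp_path):
        f1, f2 = tmp_path / "a.csv", tmp_path / "b.csv"
        _write_csv(f1, [(0, 0, 10, 1.0)])
        _write_csv(f2, [(0, 0, -10, 2.0)])
        ms = load_thickness_annotations([f1, f2])
        assert len(ms) == 2

    def test_nonpositive_thickness_rejected(self, tmp_path):
        f = tmp_path / "bad.csv"
        _write_csv(f, [(0, 0, 0, -1.0)])
        with pytest.raises(SpecError):
            load_thickness_annotations([f])

    def test_missing_header_rejected(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("0,0,0,1.5\n")
        with pytest.raises(SpecError):
            load_thickness_annotations([f])


class TestAssignNearest:
    def test_single_measurement_constant(self):
        surf = sphere_surface(10.0, 2)
        field = assign_nearest(surf, [ThicknessMeasurement((50, 0, 0), 2.5)])
        assert np.all(field == 2.5)

    def test_opposite_poles_partition_at_equator(self):
        surf = sphere_surface(10.0, 3)
        ms = [
            ThicknessMeasurement((0, 0, 10), 1.0),
            ThicknessMeasurement((0, 0, -10), 2.0),
        ]
        field = assign_nearest(surf, ms)
        # brute-force oracle: nearest measurement per vertex
        pts = np.array([m.point for m in ms])
        d = np.linalg.norm(surf.vertices[:, None] - pts[None], axis=2)
        expect = np.array([m.thickness for m in ms])[np.argmin(d, axis=1)]
        assert np.array_equal(field, expect)
        # hemispheres are constant
        assert np.all(field[surf.vertices[:, 2] > 1e-9] == 1.0)
        assert np.all(field[surf.vertices[:, 2] < -1e-9] == 2.0)

    def test_values_subset_of_measurements(self):
        surf = sphere_surface(10.0, 2)
        ms = [
            ThicknessMeasurement((5, 3, 1), 1.1),
            ThicknessMeasurement((-4, 2, 7), 2.2),
            ThicknessMeasurement((0, -8, -2), 3.3),
        ]
        field = assign_nearest(surf, ms)
        assert set(np.unique(field)) <= {1.1, 2.2, 3.3}

    def test_permutation_invariance_off_ties(self):
        surf = sphere_surface(10.0, 2)
        ms = [
            ThicknessMeasurement((5.1, 3.0, 1.0), 1.0),
            ThicknessMeasurement((-4.0, 2.2, 7.0), 2.0),
            ThicknessMeasurement((0.3, -8.0, -2.0), 3.0),
        ]
        f1 = assign_nearest(surf, ms)
        f2 = assign_nearest(surf, ms[::-1])
        assert np.array_equal(f1, f2)


class TestSmoothField:
    def test_constant_field_fixed_point(self):
        surf = sphere_surface(10.0, 2)
        f = np.full(surf.n_vertices, 1.7)
        assert np.allclose(smooth_field(surf, f, 25), 1.7)

    def test_zero_iterations_identity(self):
        surf = sphere_surface(10.0, 2)
        f = np.random.default_rng(0).uniform(1, 2, surf.n_vertices)
        assert np.array_equal(smooth_field(surf, f, 0), f)

    def test_maximum_principle_two_valued(self):
        surf = sphere_surface(10.0, 3)
        f = np.where(surf.vertices[:, 2] > 0, 1.0, 2.0)
        out = smooth_field(surf, f, 10)
        assert out.min() >= 1.0 - 1e-12 and out.max() <= 2.0 + 1e-12
        # smoothing creates a monotone band across the equator
        z = surf.vertices[:, 2]
        bins = np.linspace(-4, 4, 9)
        means = [out[(z >= a) & (z < b)].mean() for a, b in zip(bins[:-1], bins[1:])]
        assert all(b <= a + 1e-9 for a, b in zip(means[:-1], means[1:]))

    @settings(deadline=None, max_examples=20)
    @given(st.integers(min_value=1, max_value=30))
    def test_mean_preserved_on_sphere(self, iters):
        surf = sphere_surface(10.0, 2)
        f = np.random.default_rng(42).uniform(1, 3, surf.n_vertices)
        out = smooth_field(surf, f, iters)
        assert abs(out.mean() - f.mean()) / f.mean() < 0.05
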