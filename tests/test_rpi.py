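"""Diameter profiles, strength model, RPI and boundary exclusion."""

import numpy as np
import pytest

from aaarpi.errors import SpecError
from aaarpi.primitives import tube_surface
from aaarpi.rpi import (
    PatientFactors,
    StrengthModelParams,
    boundary_exclusion,
    diameter_profile,
    nord_field,
    rpi_field,
    voxel_radius_error_percent,
    wall_strength,
)


class TestDiameterProfile:
    def test_cylinder(self):
        tube = tube_surface(25.0, 100.0, n_circ=96, n_axial=30)
        dp = diameter_profile(tube)
        assert dp.diameters == pytest.approx(50.0, rel=0.01)
        assert dp.nord_max == pytest.approx(1.0, rel=0.01)

    def test_phantom_truth_recovery(self, small_geometry, small_phantom):
        geom, _ = small_geometry
        _, _, truth = small_phantom
        dp = diameter_profile(geom.external_wall)
        assert dp.max_diameter == pytest.approx(truth.max_diameter, rel=0.05)
        assert dp.neck_diameter == pytest.approx(truth.neck_diameter, rel=0.05)
        assert dp.nord_max == pytest.approx(truth.nord_max, rel=0.05)

    def test_too_few_stations_rejected(self):
        tube = tube_surface(10.0, 3.0, n_circ=24, n_axial=4)
        with pytest.raises(SpecError):
            diameter_profile(tube)


class TestNordField:
    def test_cylinder_unity(self):
        tube = tube_surface(25.0, 100.0, n_circ=64, n_axial=25)
        dp = diameter_profile(tube)
        nf = nord_field(tube, dp)
        assert nf == pytest.approx(1.0, rel=0.02)

    def test_field_max_equals_ratio(self, small_geometry):
        geom, _ = small_geometry
        dp = diameter_profile(geom.external_wall)
        nf = nord_field(geom.external_wall, dp)
        assert nf.max() == pytest.approx(dp.nord_max, rel=1e-9)


class TestWallStrength:
    def test_reference_point_female_history(self):
        # ILT=0, NORD at the model's centering value
        pf = PatientFactors("female", True)
        s = wall_strength(np.array([0.0]), np.array([2.46]), pf)
        # 71.9 + 37.9*0.81 - 21.3/2 - 19.3/2 = 82.299 N/cm2 = 0.823 MPa
        assert s[0] == pytest.approx(0.823, abs=0.0005)

    def test_sex_difference(self):
        ilt = np.array([5.0])
        nord = np.array([2.0])
        m = wall_strength(ilt, nord, PatientFactors("male", False))
        f = wall_strength(ilt, nord, PatientFactors("female", False))
        assert (m - f)[0] == pytest.approx(0.193, abs=1e-9)

    def test_monotone_decreasing_in_ilt_and_nord(self):
        pf = PatientFactors("male", False)
        ilt = np.linspace(0, 30, 50)
        s_ilt = wall_strength(ilt, np.full(50, 2.0), pf)
        assert np.all(np.diff(s_ilt) <= 1e-12)
        nord = np.linspace(1.0, 3.5, 50)
        s_nord = wall_strength(np.full(50, 5.0), nord, pf)
        assert np.all(np.diff(s_nord) <= 1e-12)

    def test_floor_applies(self):
        pf = PatientFactors("female", True)
        s = wall_strength(np.array([100.0]), np.array([6.0]), pf)
        assert s[0] == pytest.approx(0.10)

    def test_negative_ilt_rejected(self):
        with pytest.raises(SpecError):
            wall_strength(np.array([-1.0]), np.array([2.0]), PatientFactors("male", False))

    def test_unit_conversion_applied_once(self):
        # with all offsets zeroed, ILT=0, NORD=0: strength = intercept N/cm2
        params = StrengthModelParams(ilt_offset=0.0, nord_offset=0.0)
        pf_neutral = PatientFactors("male", True)  # +1/2 both, cancel 21.3 vs 19.3 partly
        s = wall_strength(np.array([0.0]), np.array([0.0]), pf_neutral, params)
        expect = (71.9 - 21.3 * 0.5 + 19.3 * 0.5) * 0.01
        assert s[0] == pytest.approx(expect, rel=1e-12)


class TestRpi:
    def test_ratio(self):
        rpi, mx = rpi_field(np.array([0.5]), np.array([1.0]))
        assert rpi[0] == 0.5 and mx == 0.5

    def test_equal_fields_give_unity(self):
        s = np.random.default_rng(1).uniform(0.2, 1.0, 50)
        rpi, mx = rpi_field(s, s)
        assert mx == pytest.approx(1.0)

    def test_zero_stress_zero_rpi(self):
        rpi, mx = rpi_field(np.zeros(10), np.ones(10))
        assert mx == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        sig = rng.uniform(0.1, 1, 20)
        st = rng.uniform(0.5, 2, 20)
        r1, m1 = rpi_field(sig, st)
        r2, m2 = rpi_field(7.7 * sig, 7.7 * st)
        assert np.allclose(r1, r2) and m1 == pytest.approx(m2)


class TestBoundaryExclusion:
    def test_zero_distance_empty(self):
        pts = np.column_stack([np.zeros(50), np.zeros(50), np.linspace(0, 100, 50)])
        assert not boundary_exclusion(pts, 0.0).any()

    def test_full_length_rejected(self):
        pts = np.column_stack([np.zeros(50), np.zeros(50), np.linspace(0, 100, 50)])
        with pytest.raises(SpecError):
            boundary_exclusion(pts, 60.0)

    def test_spike_at_cap_excluded(self):
        z = np.linspace(0, 100, 101)
        pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        sigma = np.where((z < 2) | (z > 98), 10.0, 1.0)  # artificial cap spikes
        strength = np.ones_like(z)
        mask = boundary_exclusion(pts, 10.0)
        _, peak = rpi_field(sigma, strength, mask)
        assert peak == pytest.approx(1.0)
        _, peak_all = rpi_field(sigma, strength, None)
        assert peak_all == pytest.approx(10.0)


def test_voxel_radius_error():
    assert voxel_radius_error_percent(0.625, 25.0) == pytest.approx(2.5)
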