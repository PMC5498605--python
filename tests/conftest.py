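"""Shared fixtures: voxelized primitives and a small analysis phantom.

Expensive artifacts (remeshed surfaces, geometries, meshes) are session
scoped so the suite builds each of them once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("det", derandomize=True, deadline=None)
_hyp_settings.load_profile("det")

from aaarpi.geometry import build_geometry
from aaarpi.labelmap import LabelMapVolume
from aaarpi.phantom import PhantomSpec, generate_phantom
from aaarpi.surface import extract_surface


def voxel_sphere(radius: float = 20.0, spacing: float = 1.0) -> LabelMapVolume:
    n = int(np.ceil(2 * (radius + 3) / spacing)) + 1
    c = 0.5 * (n - 1) * spacing
    ax = spacing * np.arange(n)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    vox = ((X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2 <= radius**2).astype(np.uint8)
    return LabelMapVolume(vox, (spacing, spacing, spacing))


@pytest.fixture(scope="session")
def sphere_labelmap():
    return voxel_sphere()


@pytest.fixture(scope="session")
def sphere_surface_extracted(sphere_labelmap):
    return extract_surface(sphere_labelmap)


# A small eccentric-lumen phantom shared by the geometry/meshing/FEM tests.
SMALL_SPEC = PhantomSpec(
    neck_radius=11.0,
    max_radius=22.0,
    bulge_center_z=50.0,
    bulge_halfwidth=18.0,
    total_length=100.0,
    lumen_radius=9.0,
    lumen_eccentricity=5.0,
)


@pytest.fixture(scope="session")
def small_phantom():
    aaa, lumen, truth = generate_phantom(SMALL_SPEC)
    return aaa, lumen, truth


@pytest.fixture(scope="session")
def small_geometry(small_phantom):
    aaa, lumen, _ = small_phantom
    return build_geometry(aaa, lumen, lambda s: 1.5, target_edge=5.0)


@pytest.fixture(scope="session")
def small_mesh2(small_geometry):
    from aaarpi.meshing import mesh_regions

    geom, sf = small_geometry
    return mesh_regions(geom, sf, order=2)


@pytest.fixture(scope="session")
def fine_geometry(small_phantom):
    """Default-resolution geometry (pipeline default 3 mm target edge)."""
    aaa, lumen, _ = small_phantom
    return build_geometry(aaa, lumen, lambda s: 1.5, target_edge=3.0)


@pytest.fixture(scope="session")
def fine_mesh1(fine_geometry):
    from aaarpi.meshing import mesh_regions

    geom, sf = fine_geometry
    return mesh_regions(geom, sf, order=1)


# Three phantoms with increasing maximum ILT thickness, solved once for the
# scenario-comparison and property tests (one stiffness factorization covers
# both ILT-present load cases).
TRIO_SPECS = [
    PhantomSpec(
        neck_radius=11.0, max_radius=16.0, bulge_center_z=50.0,
        bulge_halfwidth=18.0, total_length=100.0, lumen_radius=9.0,
        lumen_eccentricity=0.0,
    ),
    PhantomSpec(
        neck_radius=11.0, max_radius=21.0, bulge_center_z=50.0,
        bulge_halfwidth=18.0, total_length=100.0, lumen_radius=9.0,
        lumen_eccentricity=3.0,
    ),
    PhantomSpec(
        neck_radius=11.0, max_radius=26.0, bulge_center_z=50.0,
        bulge_halfwidth=18.0, total_length=100.0, lumen_radius=9.0,
        lumen_eccentricity=0.0,
    ),
]


@pytest.fixture(scope="session")
def scenario_solutions():
    """Per-phantom records: geometry, meshes, FEM results and peak stresses."""
    from aaarpi.fem import (
        MMHG_TO_MPA,
        ScenarioSpec,
        excluded_peak_sigma1,
        solve_scenario,
        solve_scenarios,
    )
    from aaarpi.meshing import mesh_regions
    from aaarpi.rpi import boundary_exclusion

    p = 120 * MMHG_TO_MPA
    records = []
    for spec in TRIO_SPECS:
        aaa, lumen, truth = generate_phantom(spec)
        geom, sf = build_geometry(aaa, lumen, lambda s: 1.5, target_edge=6.0)
        mesh = mesh_regions(geom, sf, order=2)
        results = solve_scenarios(
            mesh,
            [
                ScenarioSpec.standard("ilt_pressure", p),
                ScenarioSpec.standard("wall_pressure", p),
            ],
        )
        excl = boundary_exclusion(mesh.nodes, 10.0)
        peaks = {
            name: excluded_peak_sigma1(mesh, res, excl)
            for name, res in results.items()
        }
        mesh_wall = mesh_regions(geom, sf, order=2, include_ilt=False)
        res_no = solve_scenario(mesh_wall, ScenarioSpec.standard("no_ilt", p))
        peaks["no_ilt"] = excluded_peak_sigma1(
            mesh_wall, res_no, boundary_exclusion(mesh_wall.nodes, 10.0)
        )
        records.append(
            dict(
                spec=spec,
                truth=truth,
                geom=geom,
                sf=sf,
                mesh=mesh,
                mesh_wall=mesh_wall,
                results=results,
                res_no=res_no,
                peaks=peaks,
            )
        )
    return records
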