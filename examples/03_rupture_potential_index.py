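"""From wall stress to a rupture potential index map.

Combines a solved stress field with the statistical wall-strength model
(local thrombus thickness, normalized diameter, sex, family history) and
prints the peak RPI.  RPI = stress / strength; 1 is the theoretical rupture
point.
"""

from aaarpi import (
    MMHG_TO_MPA,
    PhantomSpec,
    ScenarioSpec,
    build_geometry,
    generate_phantom,
    mesh_regions,
    solve_scenario,
)
from aaarpi.rpi import (
    PatientFactors,
    boundary_exclusion,
    diameter_profile,
    nord_field,
    rpi_field,
    wall_strength,
)
from aaarpi.vtkio import write_vtp_surface

p = 120 * MMHG_TO_MPA
spec = PhantomSpec(
    neck_radius=11.0, max_radius=21.0, bulge_center_z=50.0, bulge_halfwidth=18.0,
    total_length=100.0, lumen_radius=9.0, lumen_eccentricity=3.0,
)
aaa, lumen, _ = generate_phantom(spec)
geom, sf = build_geometry(aaa, lumen, lambda s: 1.5, target_edge=6.0)
mesh = mesh_regions(geom, sf, order=2)
res = solve_scenario(mesh, ScenarioSpec.standard("ilt_pressure", p))

nv = geom.external_wall.n_vertices
dp = diameter_profile(geom.external_wall)
nord = nord_field(geom.external_wall, dp)
patient = PatientFactors(sex="female", family_history=True)
strength = wall_strength(geom.ilt_thickness, nord, patient)
mask = boundary_exclusion(geom.external_wall.vertices, 10.0)
rpi, peak = rpi_field(res.nodal_sigma1[:nv], strength, mask)

print(f"max NORD          : {dp.nord_max:.2f}")
print(f"strength range    : {strength.min():.3f} .. {strength.max():.3f} MPa")
print(f"peak wall stress  : {res.nodal_sigma1[:nv].max():.4f} MPa")
print(f"peak RPI          : {peak:.3f}  (1.0 = theoretical rupture)")

surf = geom.external_wall.copy()
surf.vertex_fields.update(
    {"ilt_thickness_mm": geom.ilt_thickness, "nord": nord,
     "strength_mpa": strength, "rpi": rpi}
)
write_vtp_surface(surf, "rpi_results.vtp")
print("wrote rpi_results.vtp (per-vertex ILT thickness, NORD, strength, RPI)")
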