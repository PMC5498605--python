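# Methods

`aaarpi` estimates the rupture potential of an abdominal aortic aneurysm
(AAA) from segmented images: it computes the maximum principal stress in
the aneurysm wall under blood pressure with a linear finite-element model,
estimates the local wall strength from a statistical model, and reports the
rupture potential index (RPI), the pointwise ratio of the two.  This note
records the models, the numerical choices and their rationale, and what the
synthetic phantoms do and do not establish.

## Why a linear, material-free stress analysis

An image of an aneurysm shows the *deformed* geometry, loaded by the blood
pressure at acquisition.  For such a configuration the wall stress must
balance the applied pressure — the structure is close to statically
determinate — so the stress field is fixed by geometry and load and depends
only weakly on the constitutive law.  The package therefore runs a single
small-strain linear solve on the imaged geometry (no inverse zero-pressure
reconstruction, no hyperelasticity), with nominal constants
E_wall = 1 MPa, E_ILT = 0.05 MPa, ν = 0.49 for both regions.

Two caveats bound this argument, and the test suite measures both:

* **Uniform scaling.** Multiplying every modulus by a constant leaves the
  stress field unchanged to round-off (verified in the suite).  This is the
  exact sense in which no patient-specific stiffness is needed.
* **Wall/thrombus stiffness ratio.** The split of load *between* the wall
  and the intraluminal thrombus (ILT) does depend on their relative
  stiffness.  With a thrombus an order of magnitude thicker than the
  1.5 mm wall, varying E_wall/E_ILT from 5 to 50 moves the excluded-peak
  wall stress by roughly a third (≈0.10→0.16 MPa on a mid-size phantom):
  a thrombus only 5× softer than the wall carries a hoop-load share of
  order E_ILT·T_ILT/(E_wall·t_wall) ≈ 2 and shields the wall appreciably.
  This is genuine mechanics, not discretization error (it persists at
  ν = 0.499 and under refinement).  Notably, the *scenario equivalence*
  below holds at every ratio tested.

## Loading scenarios

Three scenarios reflect the uncertain mechanical role of the thrombus:

1. `ilt_pressure` — wall + ILT meshed, 120 mmHg on the ILT luminal surface;
2. `wall_pressure` — same mesh, pressure applied on the internal wall
   surface, bypassing (but keeping) the thrombus;
3. `no_ilt` — wall only, pressure on the internal wall surface.

On phantoms spanning thin to thick thrombus, the excluded-peak wall stress
of scenarios 1 and 2 agrees to ~1.5–3% (wall loading slightly higher, the
difference growing with thrombus thickness), while
removing the thrombus raises the peak severalfold, increasingly so for
thicker thrombus.  Both behaviours are asserted by the acceptance tests.

Pressure defaults to 120 mmHg and is converted with 1 mmHg = 133.322 Pa.
Loads are dead loads (no follower-pressure geometric nonlinearity),
consistent with the small-displacement framing.

## Pipeline geometry

* **Inputs.** Binary AAA and lumen label maps (NRRD/MetaImage via
  SimpleITK), or a parametric phantom (below).  An optional rigid
  registration aligns a second modality's label map: centroid +
  principal-axes initialization (all four proper sign choices scored by
  Dice), refined by trimmed point-to-point ICP on the extracted surfaces;
  spherically degenerate moments fall back to centroid-only and are
  flagged.  Only rigid alignment is offered — label maps carry no
  information that could constrain a deformable match.
* **Subtraction.** The lumen is clipped into the AAA label, then
  subtracted; the remainder (wall + thrombus solid) is the meshing domain.
* **Surface extraction.** Marching cubes at iso-level 0.5 after a 1-voxel
  Gaussian pre-smoothing of the binary volume (the raw binary isosurface
  traces voxel staircases and overestimates area by ~8%; pre-smoothing
  brings sphere area and volume within 1–2% of closed forms).  Labels that
  touch the axial ends of the volume yield open tubes; caps come later.
* **Remeshing.** Incremental isotropic remeshing (edge split/collapse/flip,
  area-weighted tangential relaxation, back-projection) drives edges to a
  uniform target (default 3 mm); open boundary loops are preserved.  A
  first-order normal offset restores the enclosed volume lost to chord
  sagitta at coarse targets (kept within 1%).
* **Wall thickness.** Sparse point measurements (CSV `x,y,z,thickness_mm`)
  are assigned to vertices by Euclidean nearest measurement (a Voronoi-like
  partition; ties break to the lowest index), then relaxed by 10 umbrella
  (uniform-weight neighbour-average) smoothing iterations, which obey a
  discrete maximum principle.  Uniform rather than cotangent weights are a
  deliberate simplification; on the near-uniform remeshed surfaces the
  difference is small, but it is a known deviation risk on irregular
  meshes.  A single measurement means constant thickness; the default
  constant is 1.5 mm.
* **Internal wall.** External vertices move inward along angle-weighted
  vertex normals by the local thickness; connectivity is preserved.
  Fold-over or global inversion raises an error rather than repairing
  silently — for a risk tool a loud failure beats a quietly mangled wall.
* **Thrombus surfaces.** The luminal surface is the smaller connected
  component of the remeshed shell boundary (components classified by
  enclosed volume).  Luminal vertices closer than 1 mm to the internal wall
  are pushed away (moving the lumen, not the wall) until the gap is
  ≥ 1 mm — vertices are pushed 2% past the target so the piecewise-linear
  surface between vertices clears the minimum too.  ILT thickness is the
  nearest-point distance from internal-wall vertices to the luminal
  surface (not the along-normal distance; for nested, smooth surfaces the
  two differ negligibly and nearest-point is unambiguous at high
  curvature).
* **Size field.** A 1 mm structured lattice stores the requested element
  size: wall thickness / n_layers (default 2) in a band around the wall,
  and inside the thrombus a sine-profile growth toward the mid-layer
  (default 3×) between the near-wall size and the luminal surface
  resolution.

## Tetrahedral meshing

Because the internal wall is an offset of the external wall with identical
connectivity, the wall meshes exactly as a stack of prism layers split into
tetrahedra with globally consistent quad diagonals (lowest-global-index
rule); the thrombus extrudes from the internal wall to a sheet mapped onto
the luminal surface.  Each internal-wall vertex maps by ray casting toward
the local lumen cross-section centroid (the natural O-grid direction for
tubular anatomy); near-tangent hits at the cut ends are rejected by a
window around the nearest-point distance, boundary columns pin to the
luminal boundary rings with the same in-plane direction, and two
smooth+reproject sweeps iron residual kinks.  The wall/ILT interface shares
nodes by construction — loads transmit without tie constraints.

Layer counts: the wall uses thickness/size layers from the size field (≥ the
configured n_layers); the thrombus uses at least three layers so the
fine–coarse–fine grading exists, capped so thin columns keep ≥ ~0.33 mm
heights.  Lateral (in-plane) resolution is inherited from the remeshed
surfaces and deliberately coarser than the through-thickness size: honoring
a 0.75 mm isotropic size everywhere would produce meshes of several hundred
thousand quadratic elements, far beyond a single-CPU sparse direct solve.
This decoupling is the package's principal departure from an unstructured
size-field mesher, and the mesh-convergence test (refined size field moves
the excluded peak < 10%) bounds its effect.

Element quality: on default-resolution phantom meshes the minimum scaled
Jacobian stays above 0.05.  Extreme phantoms (27 mm maximum radius with
strong lumen eccentricity) can dip to ~0.02 in thrombus interior slivers
where many wall columns converge onto a small lumen; volumes remain
strictly positive and the FEM is unaffected, but quality-sensitive users
should lower the lateral target for such shapes.

## Finite elements

Displacement-only 4-node (linear) and 10-node (quadratic, default)
tetrahedra; quadratic elements use the 4-point Gauss rule (exact for
straight-sided elements).  A hybrid displacement–pressure formulation is
not implemented; at the default ν = 0.49 quadratic elements are accurate,
and a warning is issued if linear elements are combined with ν ≥ 0.45
(locking).  All translations are fixed on both end-cap node sets — the most
constrained reading of "fixed ends", accepted because the resulting
concentrations are excluded anyway.  The assembled system is solved with
SuperLU; the two ILT-present scenarios share one factorization.  Solver
quality is checked per solve: reactions at the fixed caps balance the
applied load to < 1e-6 relative.

Nodal maximum principal stress is recovered by volume-weighted averaging of
element centroid stresses *within the wall region only* (averaging across
the interface would dilute wall stress with thrombus values), followed by
eigen-decomposition.  Peaks are reported after excluding nodes within
10 mm of either constrained end (the default; stress there reflects the
artificial boundary conditions).

Verification: single-element stiffness matches an independent symbolic
(energy-derivative) assembly; constant-strain patch tests are exact; a
thick-walled cylinder (a = 23.5, b = 25 mm, 120 mmHg) reproduces the Lamé
inner-surface hoop stress p(a²+b²)/(b²−a²) within 5% at mid-height.

## Wall strength and RPI

Strength follows the published population model (N/cm², converted ×0.01 to
MPa):

    strength = 71.9 − 37.9(√ILT_cm − 0.81) − 15.6(NORD − 2.46)
               − 21.3·HIST + 19.3·SEX

with ILT the local thrombus thickness in cm, NORD the local normalized
diameter, HIST = ±½ (family history), SEX = ±½ (male positive).  The
constants are configuration with these defaults and are echoed into every
run log.  NORD uses the local equivalent-area diameter 2√(A/π) from 1 mm
axial cross-sections divided by the neck diameter (mean over the proximal
10% of stations); the maximum-based scalar is also reported.  A strength
floor of 0.10 MPa guards against negative strengths when the model is
evaluated outside its fitted covariate range; floor events are logged.
RPI = σ₁/strength per vertex; the reported maximum uses the same 10 mm
boundary exclusion.  RPI ≥ 1 is flagged as the theoretical rupture point.

## Synthetic phantoms

The phantom is a tube with a Gaussian-bump outer radius profile
r(z) = r_neck + (r_max − r_neck)·exp(−((z−z_c)/w)²) and a straight
cylindrical lumen whose axis shifts laterally by up to the configured
eccentricity at the bulge — giving a one-sided thick thrombus as in typical
fusiform AAAs.  Default voxel spacing is 0.625 × 0.625 × 2 mm, matching
routine abdominal CT.  Because the profile is analytic, maximum diameter,
neck diameter, NORD and maximum ILT thickness have closed forms, and the
voxelized measurements converge to them as spacing shrinks.  Phantom
dimensions in the tests (neck radius 11 mm, maximum radius 16–27 mm, i.e.
maximum diameters of 32–54 mm) bracket the diameters of surveillance-range
aneurysms.

What the phantoms do *not* emulate: imaging intensities and noise, manual
segmentation variability, branching iliac anatomy, non-cylindrical lumens,
variable wall thickness from real measurements, and cohort-scale anatomy
statistics.  Passing tests therefore establish the correctness and internal
consistency of the computational pipeline, not clinical accuracy on patient
data.

## Problem sizes and reproducibility

Scenario comparisons run on phantoms of ~100 mm length at a 5–6 mm lateral
target (≈15–25k quadratic-mesh nodes, 45–75k DOF), chosen so a full
three-phantom, two-scenario comparison completes in minutes on one CPU;
the geometry-only checks use the default 3 mm target.  All randomness
(probe sampling, optional surface noise) flows from explicit integer seeds;
identical configuration and seed reproduce byte-identical summaries.

## Known limitations

* Linear kinematics on the deformed geometry; no residual stress, no
  fluid–structure interaction, no zero-pressure reconstruction.
* Displacement-only elements: exactly incompressible materials (ν = 0.5)
  are not representable.
* The extrusion mesher requires the wall to be an offset of the external
  surface and the lumen to be star-shaped about its centerline per
  cross-section — true for the supported anatomy model, not for arbitrary
  solids.
* Wall stress depends materially on the wall/thrombus stiffness ratio (see
  above); reported stresses use the nominal ratio 20.
* The strength model is an extrapolating statistical fit; outside its
  fitted range the 0.10 MPa floor applies.
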