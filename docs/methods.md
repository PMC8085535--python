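# Methods

This note documents the models, defaults and numerical choices behind
`tkrfem`, and what the synthetic test bed does and does not show about real
implanted knees. Units are the consistent mm–N–MPa system (moments N·mm,
angles deg, time s) everywhere.

## Coordinate frame and sign conventions

One model frame is used throughout: `x` medial-lateral (the flexion axis;
medial = −x for the right knee modeled here), `y` anterior-posterior
(the varus-valgus axis; anterior = +y), `z` vertical (joint
distraction-compression; proximal = +z). Motion-lab data recorded in an
x-forward/y-right/z-up frame are converted at ingestion by the fixed
permutation `LAB_TO_MODEL`. Keeping a single internal frame, with lab-frame
conversion confined to ingestion, avoids per-module sign conventions.

Malalignment sign conventions: varus drops the medial side (rotation about
−y), internal rotation turns the anterior face medially (rotation about +z).
A positive applied My loads the lateral compartment.

## Synthetic geometry

The generator builds a six-part assembly: two spherical femoral condyles
(radius R_c = 20 mm, centers ±23 mm about the midline) joined by a box
bridge; a 76 × 50 × 12 mm insert block whose top carries two spherical dish
recesses (radius R_d = 24 mm, depth 3 mm) concentric with the condyles; a
flat tray; and cylindrical bone stubs. The initial apex gap between condyle
and dish bottom is 2 mm.

Design choices:

* **Spherical condyles in spherical dishes.** Initial contact is a point at
  each dish center and the foundation contact problem has closed-form
  oracles (flat punch, sphere-on-plane). A side effect exploited by the
  solver: rotation about the condylar axis leaves the articular surface
  invariant, so flexion affects contact only through the ligaments — which
  is also roughly true anatomically, since the collaterals attach near the
  epicondyles (close to the flexion axis) and stay near-isometric.
* **Mirror symmetry.** The whole assembly is symmetric about the sagittal
  midplane x = 0, giving an exact symmetry oracle (zero varus-valgus tilt
  under symmetric loading). For this reason the fibula stub sits on the
  midplane rather than laterally — a verification aid, not an anatomical
  claim; ligament landmarks are independent of the stub geometry.
* **Dish conformity.** R_c < R_d is enforced: equal radii would give
  conforming edge contact and destroy the point-contact initialization.

Default ligament landmarks put the femoral origins just outside the
epicondyles at condyle-center height and the insertions 65–70 mm distal on
the medial tibia (MCL) and fibular head (LCL).

## Ligament model

The Blankevoort tension-only law with quadratic toe and linear region is
implemented with the quadratic branch on [0, 2εℓ]: that is the only reading
under which the force is continuous at the transition (both branches give
k·εℓ there), and the transition strain is 2εℓ by construction. εℓ defaults
to 0.03 (the classical value for collaterals); it is configurable. Stiffness
k is the bundle total; multi-strand bundles split k equally.

Sensitivity operators follow the one-at-a-time design conventions:
attachment shifts translate *both* endpoints by the same vector so L_r and
L₀ are untouched (geometry changes, pre-tension does not); reference-strain
perturbations are relative scalings ε_r·(1 ± p) that recompute L₀ with L_r
fixed (pre-tension changes, geometry does not); an absolute-offset mode
(`eps_r_abs`) exists behind a flag. Stiffness perturbations scale k.

## Materials

Compressible neo-Hookean energy Ψ = G/2(I₁−3) − G ln J + λ/2 (ln J)², with
Cauchy stress σ = (1/J)[G(B − I) + λ ln J · I] — the standard derivation
from that energy, stated explicitly so substituting another compressible
variant is a visible change. Rigid parts carry a nominal density
7.8·10⁻⁹ tonne/mm³ for solver-file completeness only; nothing quasi-static
uses inertia. The incompressible limit ν = 0.5 is rejected rather than
regularized.

## Gait boundary conditions

Ingestion reads the OpenSim storage/motion dialect (header keys, `endheader`,
leading `time` column), enforces the declared row count and tags angle units
from `inDegrees`. Filtering is a zero-phase 4th-order Butterworth low-pass,
default 6 Hz at 120 Hz sampling — the conventional gait-analysis choice; the
source material for this pipeline specifies filtering but not its
parameters, so both are configuration.

Synthetic stance-phase records are built as: axial force = trapezoidal base
(ramps over the first/last 15% of stance) plus two Gaussian bumps centered
at 20% and 80% of stance, rescaled to the requested peak force (default
2000 N ≈ 2.9 body weights for a 70 kg subject); flexion =
baseline + amplitude·sin(πs); varus-valgus moment = low-amplitude
(3000 N·mm) full-cycle sine. The trapezoidal base is deliberate: any base
curve with an interior maximum (e.g. sin) can create a spurious third force
peak at mid-stance for sharp bump widths. Pattern constants: bouncy has
narrower bumps (abrupt loading), crouch a raised valley and +20° flexion
baseline, smooth wide gentle bumps. The seed jitters bump centers by ±0.4%
stance and amplitudes by ±2%, so trials vary while peaks stay within the
±2% windows; identical seeds reproduce records bitwise.

The two-step protocol holds flexion and My at their initial values during a
settling step (default 0.1 s) while Fz ramps from zero, then appends the
time-shifted gait curves; the settle duration is configuration (unstated in
the source material).

## Volumetric meshing

`tetrahedralize` is a Delaunay-based mesher: surface vertices plus an
interior Steiner grid sized from `max_cell_volume`, Delaunay over the point
set, tets filtered by centroid containment (generalized winding number) and
refined by centroid insertion while oversized tets remain. It does **not**
perform constrained facet recovery, so boundary fidelity is exact for convex
parts and approximate near concave features; total volume is conserved to
well under 2% on the shapes used here. The overlapping-solid femoral
component (two spheres + bridge) is meshed piecewise and concatenated, since
it violates the no-self-intersection precondition of the generic mesher.
Point containment and ray-triangle intersection are vectorized numpy
implementations (no spatial index); they are exact but O(faces × points),
sized for the desk-scale meshes used here.

## Solver-file emission

The writer targets the FEBio 3.0 XML dialect (2.5 behind a flag): materials
with engineering constants, tet4 domains for deformable parts and tri3 shell
domains for rigid ones, two tied contacts plus one sliding-elastic contact
(penalty auto on, augmented Lagrangian off, friction 0 — solver defaults,
all exposed in config), three rigid cylindrical connectors with the drive
split flexion = prescribed rotation / Fz = applied force / My = applied
moment, and ligaments as discrete nonlinear springs whose force-displacement
curve is the ligament law tabulated on a strain grid from −0.05 to 0.30 with
a breakpoint at 2εℓ. Step controls: 10 increments for the settle step, one
per gait sample for the cycle, auto-stepping enabled. Floats are emitted
with `repr` (shortest round-trip) and there are no timestamps, so writing is
byte-deterministic; `summarize_feb` parses counts back and the round trip is
asserted to be the identity.

## Reduced-order contact solver

The full deformable FE contact solve is replaced by a Winkler elastic
foundation: per-face pressure p = k_f · g⁺, with g⁺ the positive part of the
penetration of the rigid femoral surface measured from each insert articular
face centroid along the face normal. The foundation modulus uses the
confined-layer formula k_f = E(1−ν)/[(1+ν)(1−2ν)h] with the insert's UHMWPE
constants and the local layer thickness h from the mesh (face to insert
bottom, ≈ 9–12 mm). Rigid-surface queries are closed-form for the analytic
surfaces (sphere set, plane) and ray-cast for general meshes; the analytic
condyle query is exact for the synthetic geometry and ~10³× faster.

Per gait sample the solver finds (u_z, φ) satisfying vertical and y-moment
equilibrium of contact plus ligament wrenches against (Fz, My), to
|r_F| ≤ 10⁻⁶·max(Fz, 1) N and |r_M| ≤ 10⁻⁶·max(|My|, 1) N·mm. The fast path
is damped Newton with a forward-difference Jacobian (steps 10⁻⁵ mm,
10⁻⁶ rad) warm-started along the cycle; when contact-set changes defeat it
(typically tilted components near My = 0, where the moment tolerance is
absolute), a nested fallback solves the monotone vertical equilibrium as an
inner scalar problem and Brent-finds the root of the outer moment residual
in φ. Samples with Fz = 0 return the lift-off pose with zero pressure.
`settle_to_contact` bisects the largest descent with penetration ≤ tol and
errors on initial interpenetration.

Pose composition is fixed: flexion about the ML axis through the condyle
centers, then varus-valgus about the AP axis through the joint-line center,
then vertical translation. Alignment perturbations transform the component
geometry in the body frame about the component's bounding-box centroid
(configurable); ligament attachments, being on the bones, do not move with
the component. The perturbation pivot and the varus-valgus connector axis
deliberately differ (component centroid vs joint line): malalignment is a
property of the implant placement, the kinematic axis of the joint. If a
tilt consumes the initial apex gap, the component is re-seated vertically
before settling — immaterial to the solution because the vertical DOF is
force-driven. "Maximum contact pressure" is the per-face (elemental)
maximum, not a nodal extrapolation.

Peak metrics locate the interior local maxima of the total vertical contact
force, take the ones nearest 20% and 80% of stance (the earlier sample wins
ties), and report the maximum face pressure there; with fewer than two
interior maxima the 20%/80% indices are used directly and flagged. Stance
fraction is t/t_end of the supplied record.

## Sensitivity suite

VAR = (estimated − reference)/reference × 100, computed at full precision;
half-up rounding to 2 decimals is presentation only. The bundled reference
tables ship the published peak-pressure and VAR columns for the 33-row
ligament design and 10-row alignment design; `check_var_consistency`
recomputes every VAR cell from the pressure columns and flags three cells
where the published presentation disagrees with its own arithmetic (one
presumed typo, one forced zero, one truncated-instead-of-rounded digit).
STD in curve comparisons is the population definition by default
(switchable) — the source material does not say which it used.

`run_sensitivity` rebuilds an independent model per row (no state leakage),
re-settles, runs the gait cycle and reports VARs against the recomputed
reference row; per-row convergence failures are recorded without aborting
the batch.

## Problem sizes and determinism

Default test-bed sizes: insert articular grid 61 × 41 (≈ 1200 contact faces
in the dishes), 101-sample gait records, 2500-face foundation grids for the
contact oracles, coarse 17 × 11 / subdivision-1 geometry for volume-meshing
and solver-file tests. These sizes put every closed-form oracle within its
1% band while keeping a full 43-row sensitivity sweep under half a minute.
All randomness flows through explicit integer seeds (numpy default_rng);
hypothesis-based property tests are seeded by example generation and carry
no hidden state between runs.

## What the synthetic test bed does not show

* **Absolute pressures.** Sphere-in-dish contact at foundation stiffness
  k_f ≈ 600 MPa/mm concentrates load far more than a conforming implant:
  peak pressures of ~40 MPa versus the ~3–8 MPa typical of validated
  subject-specific models. Directions, rankings and invariances (load
  control, symmetry, monotonicity) are meaningful; magnitudes are not.
* **Subject-specific effects.** Published sensitivity magnitudes (e.g. the
  206% internal-rotation increase) depend on the subject's implant geometry,
  initial alignment and measured gait; the package reproduces their VAR
  arithmetic exactly and their directions qualitatively (varus tilt and
  axial-plane rotation raise single-compartment peak pressure; slack-LCL
  perturbations do nothing), not their values.
* **Full FE fields.** The foundation solver yields contact pressure, force
  and center of pressure — not internal stress fields, friction or
  large-sliding kinematics. The exported FEB file is the handoff point to a
  full solver; no acceptance path requires that solver to be present.
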