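# tkrfem

A pipeline for building and analyzing subject-specific finite-element models
of a **total knee replacement (TKR)**. After knee arthroplasty, load
distribution on the polyethylene tibial insert drives wear, loosening and
revision risk, and it is sensitive to surgical choices — implant alignment
and the state of the retained collateral ligaments. `tkrfem` automates the
model-construction chain (geometry, materials, ligaments, contacts,
connectors, gait boundary conditions, solver-file export) so that "what-if"
and one-at-a-time sensitivity studies over those choices can be scripted
instead of hand-built, and ships a reduced-order contact solver so the whole
chain runs and is testable without an external FE binary.

It is aimed at computational-orthopaedics researchers prototyping knee
contact-mechanics studies, and runs entirely on synthetic, parametric
geometry and gait data when no subject data are at hand.

## The model

**Parts and materials.** Six parts: femur, tibia, fibula and the tibial tray
as rigid bodies; the CoCrMo femoral component (E = 210 000 MPa, ν = 0.3) and
UHMWPE tibial insert (E = 1 200 MPa, ν = 0.46) as deformable compressible
neo-Hookean solids with strain energy

    Ψ(F) = G/2 (I₁ − 3) − G ln J + λ/2 (ln J)²,

where I₁ = tr(FᵀF), J = det F, and E = 2G(1+ν), λ = 2Gν/(1−2ν).

**Ligaments.** The collaterals (MCL, LCL) survive the arthroplasty and are
modeled as tension-only nonlinear springs (Blankevoort form):

    f(ε) = 0                ε < 0
    f(ε) = k ε² / (4 εℓ)    0 ≤ ε ≤ 2εℓ
    f(ε) = k (ε − εℓ)       ε > 2εℓ

with ε = (L − L₀)/L₀ and zero-load length L₀ = L_r/(ε_r + 1) from the
reference strain at full extension. Defaults: MCL k = 8250 N, ε_r = 0.04;
LCL k = 6000 N, ε_r = −0.05; εℓ = 0.03.

**Kinematics and loading.** Three enabled degrees of freedom on the femur
chain: prescribed flexion about the medial-lateral axis, vertical translation
driven by the axial joint force Fz, varus-valgus rotation driven by the
moment My. A two-step protocol settles the femoral component onto the insert
before the gait cycle plays. Gait records are read from OpenSim .sto/.mot
tables or synthesized: four stance patterns (normal, bouncy, crouch, smooth)
with the two axial-force peaks at 20% and 80% of stance.

**Contact.** The exported FEBio-format model uses rigid ties
(femur/component, tray/insert) plus a sliding-elastic tibiofemoral
interface. The built-in reduced-order solver replaces the full FE solve with
a Winkler elastic foundation on the insert's articular faces
(p = k_f · penetration, k_f from the confined-layer formula) and solves
vertical-force and varus-valgus-moment equilibrium per gait sample.

**Sensitivity machinery.** One-at-a-time perturbation grids — 5 mm ligament
attachment shifts, ±5/±10% reference-strain and ±10% stiffness scalings
(33 rows), and femoral-component malalignment of 1–5° varus/valgus tilt and
internal/external rotation (10 rows) — with results expressed as relative
percentile variations, VAR = (estimated − reference)/reference × 100.

## Worked example

```python
from tkrfem import build_synthetic_contact_model, peak_metrics, run_gait, synth_gait
from tkrfem.sensitivity import round_half_up, var_pct

bc = synth_gait("normal", peak_force=2000.0, n_points=101, seed=1)
model = build_synthetic_contact_model()
traj = run_gait(model, bc)
m = peak_metrics(traj, bc)
print(f"P1 = {m['P1']:.2f} MPa at sample {m['i1']}, "
      f"P2 = {m['P2']:.2f} MPa at sample {m['i2']}")
print(f"peak-2 contact force = {m['F2']:.1f} N")
print(f"VAR example: {round_half_up(var_pct(8.98, 2.93), 2)} %")
```

prints

```
P1 = 40.24 MPa at sample 20, P2 = 41.69 MPa at sample 80
peak-2 contact force = 2003.9 N
VAR example: 206.48 %
```

The two pressure peaks land at 20% and 80% of stance (the loading-response
and pre-swing force maxima). The peak contact force slightly exceeds the
2000 N applied axial force because the taut MCL pulls the femur down. The
VAR line reproduces, from the bundled reference peak-pressure table, the
published 206.48% pressure increase under 5° internal rotation of the
femoral component. Absolute pressures on the synthetic sphere-in-dish
geometry are higher than on a real conforming implant; directions and
rankings, not magnitudes, are the meaningful output at this scale (see
`docs/methods.md`).

The same pipeline is scriptable from the shell:

```sh
tkrfem synth-geom --out geom/                 # six STL parts + manifest
tkrfem gait-synth --pattern bouncy --peak-force 2600 --out bc.csv
tkrfem build-feb --bc bc.csv --out model.feb  # FEBio-format model file
tkrfem run --bc bc.csv --out results/
tkrfem sensitivity --design alignment_table --bc bc.csv --out table.csv
```

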