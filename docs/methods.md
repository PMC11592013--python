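# Methods

`osteoimpact` simulates a rigid cylinder striking a layered cortical/
trabecular bone structure with an explicit finite-element solver. This note
records the models, the numerical choices, and what the synthetic fixtures
do and do not represent.

## Constitutive model

Both bone phases are isotropic, linear-elastic, J2-plastic solids with
multilinear isotropic hardening. The elastic constants are the Misch
type II values used throughout: cortical E = 13.7 GPa, cancellous
E = 5.5 GPa, ν = 0.3, ρ = 2.12 g/cm³ for both phases. (The identical
cancellous density is kept as printed in the source material tables; it is
plausibly a duplicate of the cortical value, but no better number is
available and the trabecular mass fraction is small.)

Cortical bone is strain-rate sensitive through the Cowper–Symonds
overstress law, ε̇pl = D·(R−1)ⁿ with D = 360.7 s⁻¹ and n = 4.61, inverted
as R = 1 + (ε̇pl/D)^(1/n). R multiplies the whole quasi-static hardening
curve (the standard overstress composition; the composition rule is a
package choice, as only the law and its constants are given). Trabecular
bone is rate-independent — it fails secondarily, after the cortical shell,
and its rate sensitivity has little influence on the fracture outcome.

The hardening curves themselves are **calibration defaults**, not measured
tables: cortical yield 110 MPa rising linearly to 180 MPa at 2% equivalent
plastic strain (so the 1000 s⁻¹ dynamic curve peaks near 250 MPa, the top
of the plotted stress range in the reference data), trabecular 30 MPa,
flat. Both are plain `[[ε̄pl, σ], ...]` tables in the material card and can
be overridden from configuration.

Stress integration is an elastic predictor with radial return onto the
rate-scaled yield surface. The plastic rate entering R is the implicit
Δε̄pl/dt of the same increment; the scalar residual is monotone in the
plastic multiplier, so a bisection solve is unconditionally robust
(closed-form return is used in the rate-free linear-hardening case).
Incremental objectivity uses the Cayley rotation R = (I−W/2)⁻¹(I+W/2) of
the spin increment, which is exactly orthogonal, so pure rigid rotation
preserves stress invariants to machine precision. The kinematics are
small-strain on the reference configuration; failure strains here are ≤6%,
which keeps the geometric error small and lets all element operators be
precomputed once.

## Damage, fracture energy and element deletion

Cortical damage initiation is the ductile-rupture criterion: the initiation
measure ω accumulates Δε̄pl/ε̄pl_onset(ε̇), with the onset strain tabulated
against plastic strain rate (0.02 quasi-static falling to 0.0024 at
1000 s⁻¹) and interpolated piecewise-linearly in log₁₀(rate); rates at or
below the first tabulated nonzero rate use the quasi-static value. Only one
stress triaxiality (−p/q = 0.33, uniaxial tension) is tabulated, so the
triaxiality dependence is collapsed — a documented limitation. The rate fed
to the lookup is an exponential moving average (weight 0.1, ≈10-step
memory, seeded with the first observed rate) to suppress step-noise-driven
jumps in the onset strain.

Initiation is declared at ω ≥ 1, recording the current flow stress σ_y0.
Softening is linear in the effective plastic displacement u_pl = L_e·ε̄pl
with failure displacement u_f = 2G/σ_y0 and G = 1.54 mJ/mm², which makes
the post-onset dissipation per unit fractured area equal G independent of
element size (the point of the fracture-energy regularization; verified for
L_e ∈ {0.5, 1, 2} mm within 2%). L_e = V^{1/3}. Stress is degraded by
(1−d); elements are deleted at d ≥ 0.99 rather than 1.0 to avoid a
zero-stiffness tail (energy error below 1%). Deleted elements contribute no
internal force and are removed from the contact surface, irreversibly.
With the default curves, quasi-static single-element deletion occurs near
3% total plastic strain at L_e ≈ 1.5 mm, consistent with a 3% cortical
failure-deformation criterion read as onset at 2% plus the softening
branch.

Trabecular elements are deleted at a flat plastic-strain cap of 0.06 —
twice the 3% cortical failure deformation (the conservative reading; the
alternative 2 × 0.02 = 0.04 is available as a configuration option).

## Explicit dynamics

Central-difference leapfrog with row-sum lumped mass. Elements are 8-node
hexahedra with full 2×2×2 deviatoric quadrature and mean-dilatation (B-bar)
volumetric treatment — no volumetric locking and no hourglass modes — plus
constant-strain 4-node tetrahedra for fixtures. The tet4 is used as-is
(no nodal-patch dilatation averaging): every shipped scenario mesh is
hexahedral, and the extra machinery would serve only fixture elements.

The per-element stable increment reported by `stable_dt` is the classical
CFL estimate L_e/c_d with c_d the dilatational wave speed and L_e = V/A_max.
That estimate is *not* conservative for this element: the measured critical
increment of a fully integrated B-bar cube with row-sum lumping is
0.734·L_e/c_d. The solver therefore computes the exact per-element maximum
frequency (one batched 24×24 eigensolve at initialization) and steps at
0.9 × 2/max ω_e; by the element Rayleigh bound this is rigorously stable
for the assembled model. Selective mass scaling multiplies the mass of any
element whose stable increment falls below the target (default 10⁻⁷ s) by
(dt_target/dt_e)², reporting the affected elements and warning when the
added mass exceeds 1% of the model. A divergence monitor aborts when
kinetic energy grows more than tenfold over 100 steps above the initial
energy scale.

Energy bookkeeping: internal work is the trapezoidal f·du integral of the
assembled nodal forces (exact for the linear-in-displacement part of the
response); the contact channel is tracked as the *exact discrete pair work*
of the contact forces on the mesh and the impactor, split into the stored
pressure–overclosure potential (reversible, c ≥ 0 branch), friction loss
and an inelastic remainder. With this pairing the ledger residual reduces
to the mismatch between constitutive stress work and assembled nodal work
plus endpoint terms, and closes well within 2% of peak total energy on
every shipped scenario.

Two impulse limits stabilize the explicit contact. Tangential: the
regularized Coulomb traction is capped at half the per-step stick force
m·|v_t|/dt — uncapped, the traction flips at full magnitude around the
stick state of vibrating surface nodes and pumps energy into the mesh.
Normal: beyond zero clearance the force is capped at the larger of the
zero-clearance spring force and the impulse that sweeps the node along
with the cylinder surface — a node freshly exposed by element deletion can
lie deep inside the cylinder, and the pre-compressed penalty spring would
otherwise launch it with energy the impactor never supplied. Neither cap
alters the pressure–overclosure law itself (anchors p(c₀) = 0 and
p(0) = p₀ are exact); they bound what a single explicit step may do.

Tie constraints merge coincident (or within-tolerance) surface nodes,
which preserves rigid-body motion exactly. The far boundary of each
synthetic fixture is fully fixed (the stand-in for a far-field support).

Modal verification assembles the same B-bar stiffness with the lumped mass
into a generalized eigenproblem; a slender cantilever recovers the
Euler–Bernoulli first bending frequency within 10%, and a clamped plate's
static deflection converges monotonically toward the Kirchhoff value under
refinement (the ~6% terminal offset is the transverse shear thin-plate
theory omits; a uniform pressure is used because a point load on a 3D
continuum has no converged displacement).

## Contact and impactor

The skin between impactor and bone is not meshed; its force transmission is
an exponential pressure–overclosure law with clearance c₀ = 1.5 mm (average
skin thickness over the cheekbone) and p₀ = 100 N/mm² at zero clearance:
p(c) = p₀(e^{1−c/c₀}−1)/(e−1) on [0, c₀), zero beyond c₀, and a linear
penetration branch with slope matched at c = 0 so the contact stiffness
stays bounded (and does not control the stable increment). Friction is
regularized Coulomb with μ = 0.2, ramping to the cap over a slip speed of
1 mm/s to avoid stick–slip chatter.

Contact is node-to-analytic-surface against the exact finite cylinder
(200 mm × Ø40 mm, 2 kg), with tributary areas from the alive exterior
faces; the impactor receives the exact opposite resultant, so contact
conserves linear momentum to round-off. The impactor free-flies in
translation under the reaction; its rotational degrees of freedom are
frozen — the shipped scenarios are normal-incidence and near-symmetric, so
the net torque is negligible, and a tumbling impactor is out of scope.
During deletion bursts the exterior surface is refreshed every few steps
rather than every step; the transient staleness affects only which nodes
carry tributary area for a few sub-microsecond increments.

## Synthetic geometry — what it stands for and what it does not

The real study geometry (a licensed full-body head model with CT-derived
maxillary bones) is not available. The generators build structured,
deterministic stand-ins with the structural features the analysis needs:

* **Layered plate** (default 40×40 mm, 1.5 mm cortical skins over a 7 mm
  trabecular core, 1.5 mm elements ⇒ 5103 hexes): the Misch type II
  two-layer architecture at the study's mesh resolution, struck on the top
  face. The default support fixes the two edges parallel to the impactor
  axis ("bridge") — a strut spanning two abutments, the way the cheekbone
  bridges maxilla and temporal bone — which gives the bending-plus-crushing
  competition and, at the calibrated defaults, the observed contrast:
  at 5 km/h the plate responds elastically (no damage), at 20 km/h the
  striker opens a through-thickness crush path under its footprint. Fully
  clamped edges are a configuration option (stiffer, crush-only, arrests
  the striker at every study speed).
* **Arch**: a curved cortical-shell/trabecular-core pillar between two
  fixed abutments, for the bending-plus-crushing competition a strut-like
  cheekbone exhibits; proportions are synthetic defaults, not anatomy.
* Single elements and bars for verification rigs.

Passing tests on these fixtures validates the *mechanics* — material
response, damage regularization, contact, conservation — not anatomical
force levels or fracture-line geometry: absolute peak forces and fracture
paths depend on the unavailable head model and are treated qualitatively
only. Two desk-scale fidelity gaps are worth stating plainly. First, at
5 km/h the synthetic plate shows *no* damage initiation at all (not merely
no fracture): the skin-surrogate layer spreads the ~3.5 kN filtered force
over ~600 mm², keeping cortical stress below the 110 MPa yield; localized
low-speed damage requires the thin curved walls of the real zygoma.
Second, severity ordering in impact speed is robust in the damaged volume
and in the unfiltered peak force, but the CFC180-filtered peak is *not*
monotone once the plate perforates — the transmitted pulse truncates when
the structure fails, a pulse-duration effect absent from the anatomical
model where surrounding intact structure keeps loading the striker. What
does hold at the calibrated defaults: no fracture at 5 km/h, a
through-thickness crush path at 20 km/h, and monotone damaged volume.

## Problem sizes and run windows

The calibrated default plate scenario runs 5 ms of physical time
(≈15,000 explicit steps at dt ≈ 3.3×10⁻⁷ s), which contains the entire
force pulse on this fixture; a full 0.02 s window is a configuration
option. Verification runs at 5 km/h use a 2.5 ms window (the cylinder has
separated and is rebounding well before 2 ms). The four-speed severity
sweep in the test suite uses a reduced 30×30×8 mm plate and a 2 ms
window — the qualitative ordering is insensitive to the fixture size, and
four full-size solves would dominate the suite's runtime. History channels
are sampled every 10 µs (CFC180-safe); snapshots every 0.5 ms.

## Known limitations

* Isotropic, homogeneous bone; real bone is anisotropic and heterogeneous.
* One triaxiality row in the rupture table; compressive/shear failure
  states reuse the uniaxial-tension onset strain.
* Small-strain kinematics with rotated stress, not finite strain.
* No crack-path tracking beyond element deletion; deleted-element
  components are a resolution-limited fracture surrogate.
* No deformable–deformable contact; only the impactor contacts the bone.
* Trabecular phase shares the printed density of cortical bone.
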