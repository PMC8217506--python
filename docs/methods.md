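# Methods

`vesselfe` is a desk-scale re-implementation of a multiscale finite-element
pipeline for cerebrovascular loading during a controlled cortical impact
(CCI): a voxel-meshed tissue block with an embedded vascular beam network is
loaded by a rigid indenter, the per-vessel axial stress history is mapped
onto the tissue, and the geometry/stress statistics that link vascular
anatomy to the parenchymal stress wave are computed.  This note documents
the model, the numerical choices, and what the synthetic data do and do not
emulate.

## Units

All public interfaces use µm (length), ms (time), kPa (stress) and kg/m³
(density).  Internally the solver works in the consistent µm/ms/kPa system
(densities scaled by 1e-9), in which velocities in µm/ms are numerically
metres per second × 10⁻³; no unit conversion is exposed to the user.

## Synthetic angioarchitecture

The real angioarchitecture this pipeline is designed around was
reconstructed from synchrotron phase-contrast imaging of rat brain and is
not publicly deposited, so every stage runs on a synthetic stand-in that is
calibrated to the published summary statistics of that reconstruction:

* vessel diameters span 10–100 µm with a **mean of 17.85 µm**;
* the vessel **volume fraction is 5.4 %** of the tissue volume;
* vessels form branching trees with occasional cross-links.

The generator (`synthetic.generate_network`) grows bifurcating trees from
random interior roots: step lengths ~60 µm (CV 0.3), bifurcation probability
0.35 per node, branch angles ~35° ± 12° off the parent axis, small angular
jitter on continuations.  Growth stops when the accumulated conical-frustum
volume reaches the calibrated volume fraction (trees stop proportionally
short of the target to leave room for the cross-link volume); 3 % of the
segment count is then added as capillary cross-links between nearby nodes of
different trees.

**Diameter law.**  Segment diameters are drawn iid from a lognormal
truncated to [10, 100] µm whose log-mean is fitted (log-σ fixed at 0.55) so
the truncated mean equals 17.85 µm.  iid assignment is used because it is
the only scheme that preserves the fitted mean exactly regardless of tree
topology; a strict Murray-decay mode (`radius_mode="murray"`, exponent 3,
children thinner than parents) is available but cannot simultaneously pin
the printed mean, so it is not the default.  Node radii are half the
diameter of the incoming segment; per-segment diameter is defined as the sum
of the two endpoint radii and per-segment volume as the conical frustum
between them.  Branches clipped at the domain wall shorter than 5 µm are
dropped (unresolvable below the imaging scale, and degenerate as beams).

**Tissue volume.**  `generate_tissue_image` rasterizes a rounded-corner
block (or a sphere, for analytic-volume checks) into an intensity volume at
5.92 µm default voxel spacing, with foreground/background intensities
strictly separated across the default segmentation threshold of 128.

**What the synthetic data do not emulate:** real angioarchitecture is
space-filling with strong cortical penetrating-vessel anisotropy,
artery/vein hierarchy and diameter–topology correlations; the tissue is
homogeneous (no grey/white matter, CSF or skull).  Tests passing on this
data demonstrate the correctness of the mechanics and statistics machinery
and the qualitative anatomy–stress mechanisms, not quantitative prediction
for real brains.

## Meshing

`voxelize` turns a thresholded volume into 8-node hexahedra, one element per
coarse cell of `coarsen`³ voxels, included when at least half its voxels are
foreground (majority vote, unbiased in volume).  Nodes merge exactly via
integer lattice indexing.  The printed source-model statement that one
element represents "4 voxels" is not self-consistent (4 is not a cube and
48/5.92 ≈ 8.1), so coarsening is a free integer parameter; the shipped
desk-scale configuration uses 5.8 µm voxels with `coarsen=5` (29 µm
elements).  The outer surface can be smoothed by a surface-restricted
Laplacian (interior nodes never move) with a volume-preserving rescale of
the boundary; smoothing aborts if any element Jacobian turns non-positive
and enforces < 5 % total-volume drift.

`discretize_network` splits each centreline segment into equal beams no
longer than `max_len` with linearly interpolated nodal radii, conserving
length and frustum volume.  `extract_submodel` refines all elements inside
an axis-aligned box `refinement`³-fold in the parent's natural coordinates,
records (parent element, natural coordinates) for every refined node, and
clips beams to the box with interpolated cut radii; refined element sizes
below 20 µm trigger a warning (the resolution floor of the source model).

## Constitutive models

Tissue: one-term Ogden hyperelasticity,
Ψ = Σ_p (µ_p/α_p)(λ₁^α_p + λ₂^α_p + λ₃^α_p − 3), applied to the isochoric
stretches, with a volumetric penalty K(J−1) for near-incompressibility, plus
deviatoric Prony-series viscoelasticity S(t) = S∞ + ∫ G(t−T) dE_dev/dT dT,
G(t) = Σ G_i exp(−t/τ_i), on the Green–Lagrange strain, integrated with the
standard recursive exponential update (exact for piecewise-linear strain).

No single published constant set is adopted verbatim; the shipped defaults
are representative of reported rat-brain properties and are explicitly
package defaults, fully configurable:

| parameter | default | rationale |
|---|---|---|
| Ogden (µ, α) | (1.2 kPa, 4.0) | kPa-scale shear modulus, strong strain stiffening typical of grey matter |
| Prony (G_i, τ_i) | (3 kPa, 0.5 ms), (1 kPa, 5 ms) | ~3× instantaneous/long-term stiffening on impact timescales |
| density | 1040 kg/m³ | soft tissue |
| effective ν | 0.49998 (K ≈ 60 MPa) | near-incompressibility; keeps vessel axial stress under pure hydrostatic load below 1 % of the applied pressure, the regime the deviatoric-vs-total dissociation analyses require (a softer K ≈ 12 MPa penalty would leak ~4 % of hydrostatic pressure into vessels) |

Vessels are linear elastic with E = 1.4 MPa, ν = 0.38, density 104 kg/m³ as
printed in the source description.  The density is plausibly a typographical
artifact (1040 is the usual value); it is kept as printed and only affects
the (slaved) beam mass distribution, which is negligible.  With E = 1.4 MPa
the 200 kPa axial-stress threshold corresponds to 14 % axial strain.

## Explicit solver

Central-difference (symplectic-Euler) integration with one-point-integrated
hexahedra, lumped masses, and Flanagan–Belytschko-style hourglass control
with both a viscous part (coefficient 0.05 on the hourglass-mode velocity)
and an elastic part (0.2 × instantaneous shear modulus × element length on
the hourglass-mode displacement).  The elastic part carries most of the
stabilisation so that spurious dissipation of real deformation energy stays
bounded; both act on base vectors orthogonalized against the linear field,
so affine motions (including rigid rotations and translations) generate no
hourglass force.

**Timestep.**  `stable_timestep` reports the classical estimate
safety × min(element length / dilatational wave speed), beams included.  The
integrator runs at half that value: the triaxial dilatational mode of a
hexahedron is √3 stiffer than the 1D wave estimate, which numerical growth
tests confirm (instability between 0.7 and 0.9 of L/c, stability at ≤ 0.5).
Because beam nodes are slaved, the free-truss beam CFL does not apply;
instead beams bound the step through the axial-spring criterion
dt ≤ sqrt(m_min/k) with k = EA/L against the lightest tissue node (factor-2
margin below the exact 2/ω bound).

**Embedded beams.**  Beam nodes carry no degrees of freedom: their motion is
interpolated trilinearly from the host hexahedron at the natural coordinates
found by Newton inversion of the isoparametric map (tolerance 1e-10, ties on
shared faces to the lower element id, round-trip residual < 1e-9 µm).  Beams
are axial (truss) members — the bending stiffness of 5–50 µm vessels is
negligible at tissue scale and the injury metric is axial stress — with
engineering strain ℓ/ℓ₀ − 1 and force σA₀ along the current axis,
distributed to host nodes with the transposed interpolation weights
(action–reaction holds by construction); beam mass is likewise lumped onto
host nodes.

**Contact.**  The impactor is a rigid flat-tipped cylinder driven at
constant velocity to the prescribed depth, held, and optionally retracted.
Contact is a nodal penalty normal to the tip surface with stiffness
0.1 m/dt² per node and damping 0.2 of critical; a quarter-circle fillet on
the tip rim (configurable, default 60 µm at desk scale) removes the
flat-punch edge singularity that otherwise collapses coarse elements under
the rim.  The base of the block is fixed; lateral faces are free by default, with an
optional plane-strain-like mode (`lateral_bc="symmetric_y"`) that blocks
normal motion on the two y-extreme faces to emulate transverse skull
constraint.  This
desk-scale block deliberately replaces the full head model (skull and CSF
are out of scope); it preserves the loading physics the downstream analyses
need.

**Energy accounting.**  All force work is accumulated at midpoint
velocities, which makes the discrete work–energy identity exact; the
energy-balance check (default 5 %) therefore flags constraint or accounting
errors rather than quadrature noise, while blow-ups surface as element
inversion errors naming the element and time.

**Submodelling.**  A refined region re-runs with boundary-node positions
interpolated from the parent solution (trilinear in space via the stored
natural coordinates, linear in time between output frames) and the interior
integrated without contact; initial conditions are interpolated from the
parent at the window start.  For affine parent motions this reproduces the
parent field to machine precision (patch test), at any refinement.

Output is sampled every 0.01 ms: nodal positions, per-element Cauchy stress
and Green–Lagrange strain, per-beam axial stress, direction and node
positions.

## Stress mapping and statistics

* **Vessel-stress map**: each tissue element receives the maximum over
  neighbouring beams of the per-beam peak-over-time axial stress.  The
  neighbourhood is a ball (default radius: one element edge) around the
  undeformed element centroid over undeformed beam midpoints — the smallest
  neighbourhood that captures every in-element beam, frozen at the reference
  configuration for reproducibility.  Tensile-only by default (compressive
  peaks clipped at zero), since the injury comparison concerns tension; a
  signed mode exists.  Elements with no nearby beam carry NaN, never zero.
* **Threshold areas**: exceedance areas at 150/200/250/300 kPa on the
  element layer nearest a configurable coronal coordinate (mid-plane by
  default), as area (mm²) and as fraction of the ROI slice.
* **Records**: one row per beam element and output frame, joining the beam
  axial stress and current direction with the host element's stress/strain
  tensors, their first principal values and directions, deviatoric
  counterparts, and vessel-to-principal-direction angles in [0°, 90°]
  (sign-free via |cos|).  The "neighbouring tissue" of a beam is its
  midpoint's host element — the minimal reading consistent with the
  embedded coupling.
* **Statistics**: Pearson R with two-sided p; first-order partial
  correlation r_xy·z = (r_xy − r_xz r_zy)/√((1−r_xz²)(1−r_zy²)); OLS
  regression, optionally on log₁₀ stress (base 10 chosen; non-positive
  values dropped with a reported count); tension-vs-compression ROC of the
  angle (smaller angle predicts tension), AUC by the Mann–Whitney rank
  statistic with ties counted half and a stratified-bootstrap 95 % CI
  (2000 resamples by default, seeded).  Magnitude correlations are computed
  on tensile records.  No multiple-testing correction is applied (raw
  p-values are reported).

## Desk-scale study conditions

The shipped pipeline configuration simulates a 580 µm tissue block meshed at
29 µm (20³ ≈ 8000 elements) containing a default-calibration network
(~1000 segments, ~2000 beams), indented 90 µm by a 150 µm-radius impactor
(80 µm rim fillet) at 1 m/s, 2 ms simulated, sampled every 0.01 ms.  The
indentation depth stays near three element layers: deeper desk-scale
indentation concentrates shear under the rim beyond what one-point elements
at this coarseness tolerate.  Acceptance-level checks of
the generator statistics use ≥ 10⁴ segments in a 1.7 mm domain.  These sizes
keep a full pipeline run in minutes on one core while preserving several
element layers under the indenter and hundreds of vessels for the
statistics.

## Known limitations

* One-point hexahedra with hourglass control trade accuracy for robustness
  in the strongly sheared region under the indenter rim; deep indentation
  (≳ 4 element layers) with a sharp rim can still invert elements — use the
  rim fillet and finer meshes.
* The viscous part of the hourglass control dissipates energy from real
  non-affine deformation modes on coarse meshes; the energy log reports the
  hourglass share explicitly.
* The elastic hourglass term is measured on total displacement and is not
  objective under large rotations of hourglass-deformed elements (standard
  practice; irrelevant at the rotations reached here).
* Beams are trusses tied rigidly to the tissue; no vessel–tissue slip, no
  bending or internal pressure.
* Statistical records are serially correlated across frames of the same
  beam; reported p-values do not account for this (matching the source
  analysis style).
* The tension/compression ROC of the vessel angle depends on the strain
  state of the surrounding tissue.  Under (near-)uniaxial fields the angle
  to the first principal direction determines the sign of the fibre strain
  and the AUC approaches 1; desk-scale block indentation of a nearly
  incompressible solid instead produces biaxial-extension states (one
  compressed axis, two stretched) in most of the volume, where fibres at
  large angles to the first principal direction are still stretched, so the
  pipeline-level AUC is far lower than on uniaxial validation fields.  This
  is a property of the loading geometry, not of the ROC machinery.
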