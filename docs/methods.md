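# Methods

`breastfem` registers functional supine images (PET-like) onto structural
prone images (MR-like) of the breast by simulating the gravity-induced
posture change with a patient-specific finite-element model. This note
records the model, its numerical treatment, the synthetic data it is
validated on, and the design choices made where the design was genuinely
open.

## The biomechanical model

The breast is a nearly incompressible, isotropic, hyperelastic solid
attached to a rigid chest wall. Each tissue (adipose, fibro-glandular,
skin) follows the compressible neo-Hookean law with strain energy density

    psi = mu/2 (Ibar_1 - 3) + K/2 (J - 1)^2,
    Ibar_1 = J^(-2/3) tr(F^T F),   J = det F,

with the small-strain shear and bulk moduli derived from Young's modulus
E and Poisson's ratio nu by `mu = E / 2(1+nu)` and `K = E / 3(1-2nu)`.
Defaults before personalisation (literature values):

| tissue          | E (kPa) | nu   | rho (kg/m^3) |
|-----------------|---------|------|--------------|
| adipose         | 250     | 0.49 | 950          |
| fibro-glandular | 1875    | 0.49 | 1020         |
| skin            | 1000    | 0.49 | 1000         |

The fibro-glandular modulus is held at 7.5x the adipose modulus
throughout; nu = 0.49 approximates incompressibility while keeping K
finite. Lesion voxels are treated as fibro-glandular for the mechanics.

**Loading and boundary conditions.** Gravity (9.81 m/s^2) acts along the
anteroposterior axis: posteriorly in the supine posture, anteriorly in
prone. Chest-wall nodes are fixed in the anteroposterior direction, as
the physiology suggests; because that alone leaves two in-plane
translations and an in-plane rotation unconstrained, three pin
constraints remove the rigid modes (`chest_wall_fixation="all"` clamps
the wall completely instead).

**Reference state.** All images are acquired under gravity, so the
load-free geometry is unknown. It is estimated by a Sellier-type fixed
point: starting from the observed supine geometry, repeatedly
forward-solve the current guess under supine gravity and subtract the
predicted-minus-observed shape mismatch (damping factor 1.0, halved on
divergence) until the mean surface mismatch is below 0.2 mm. The
supine-to-prone map is then the prone-gravity solve of the estimated
reference, expressed as displacements of the supine nodes.

**Skin.** The skin is an incompressible neo-Hookean *membrane* of
thickness 1 mm sharing the breast surface nodes, using the tension-field
(relaxed) energy: with principal surface stretches `l1 >= l2`,

- taut (`l2 > l1^-1/2`): `t mu/2 (l1^2 + l2^2 + (l1 l2)^-2 - 3)`
- wrinkled (`l1 > 1 >= l2 sqrt(l1)`): `t mu/2 (l1^2 + 2/l1 - 3)`
- slack (`l1 <= 1`): 0.

Several design iterations motivated this. Thin solid skin hexahedra
(1 mm over 4-8 mm bulk elements) either lock under full integration —
stiffening the breast an order of magnitude and erasing the sensitivity
of nipple displacement to the bulk modulus that the inverse problem
feeds on — or, under reduced integration, invert transiently on any
Newton overshoot and throttle the line search. An unrelaxed membrane is
not quasiconvex in compression: wrinkling microstructure leaves the
discrete problem without a minimizer and Newton stalls at a residual
plateau. The relaxed energy is the accepted macroscopic model (a
membrane cannot carry compressive stress) and restored both robust
convergence and physically plausible sag. Solid-element skin remains
available (`FemConfig(skin_model="solid")` with
`meshing.add_skin_layer`).

The regime switch carries a stiffness jump of order `mu t` — an order
of magnitude above the bulk nodal stiffness — and the undeformed
reference sits exactly on the taut/slack boundary, so the tangent is
handled in the semismooth-Newton way: each Gauss point's regime is
frozen at the current iterate and the facet tangent is that branch's
Hessian. (A finite difference straddling the kink smears the jump into
a stiffness belonging to neither branch, which makes Newton chatter; a
C^1 energy blend was also tried and cured the chatter but introduced a
steep blend-gradient force that wedged strongly compressed supine
solves.)

## Discretisation and solver

8-node hexahedra on a structured lattice ("sugar-cube" meshing of the
label map; a cell becomes an element when at least half its voxels are
breast, tissue-tagged by majority vote with ties toward
fibro-glandular). Selective reduced integration — the isochoric term at
the 2x2x2 Gauss rule, the volumetric penalty at the element centre —
prevents volumetric locking at nu = 0.49. Membrane facets use a 2x2
rule. The discrete residual is the exact gradient of the
quadrature-defined energy and the bulk tangent its exact Hessian (both
are verified against finite differences in the test suite). Membrane
facet tangents are finite-differenced from the analytic forces and
projected to positive semidefinite: the relaxed energy is flat along
slack directions and its exact second derivative is only piecewise
smooth.

**Nonlinear solve.** Inexact Newton with an Armijo backtracking line
search on the total potential energy (the correct merit function for a
minimisation problem: it accepts steps on which the residual transiently
grows), inversion-guarded. Gravity is applied through an adaptive ramp:
initial step 1/5 of the load, doubled after increments converging in <=4
iterations, halved in place on failure, abandoned below 1/80. Mildly
nonlinear problems are first attempted in a single full-load step. The
convergence criterion is a relative force residual of 1e-5 (maxiter 40);
near wrinkled membrane states the PSD-projected branch tangent yields
linear convergence, so a Newton sequence that stagnates within one order
of magnitude of the tolerance is accepted — the displacement error
there is orders of magnitude below anything the registration metrics
resolve. Indefinite corners fall back to a Levenberg-damped system and,
last, a scaled gradient step.

**Linear solves.** Conjugate gradients with a two-level additive
preconditioner: 3x3 nodal block Jacobi plus a direct factorisation on a
coarsened node lattice (trilinear prolongation from every 2nd/4th/...
lattice node, chosen to keep the coarse space under ~2500 nodes). The
coarse space carries the smooth low-energy modes that Jacobi handles
worst; the combination keeps iteration counts in the low hundreds
through the 500:1 skin/adipose stiffness contrast. Dirichlet conditions
are imposed by operator masking, preserving the nodal block structure.
A direct sparse factorisation is used only on the coarse space — the
SuperLU build available here needs ~27 s for a 33k-dof tangent, which
would dominate every Newton iteration.

**Continuation in stiffness.** The deformation varies smoothly with
log E, so soft targets (E below ~10 kPa) are reached by stepping the
modulus down geometrically (factor <= 2.5) and warm-starting each
sub-solve — including the reference-state fixed point — from the
previous one; a failing step inserts the geometric midpoint. The
stiffness grid search exploits the same mechanism trial-to-trial.

## Patient-specific optimisation

A rigid Procrustes fit of three chest-wall landmarks between postures
maps the supine nipple into the prone frame; the residual distance to
the prone nipple is the target displacement Vmax that gravity alone must
explain. The adipose modulus is then found by a multi-resolution grid
search over E in (0.5, 500) kPa: 12 log-spaced coarse trials from the
stiff end (each trial runs the full supine-to-prone simulation,
fibro-glandular slaved at 7.5x), stopped early once the simulated nipple
displacement Vn satisfies |Vmax - Vn| <= 1 mm or once a trial overshoots
Vmax (monotonicity brackets the optimum and avoids ever-softer, ever
more expensive trials); then up to two rounds of 5 log-spaced refinement
points between the incumbent's grid neighbours, with the same 1 mm
stopping rule. Ties within 0.01 mm resolve to the smaller modulus. The
search treats only the adipose modulus as free; searching both tissues
independently is available but off by default, since the fixed ratio is
what makes the single-observable problem well-posed.

## Registration and evaluation

Node displacements are interpolated to a dense voxel field (barycentric
linear interpolation inside the mesh support, nearest-node values within
2 mm outside, zero beyond) and the PET-like volume is warped by backward
mapping: the forward map `x + u(x)` is inverted per voxel by fixed-point
iteration (0.1 mm tolerance, 20 iterations, field extended by its edge
values). A closed-form similarity transform from the three predicted vs
observed chest-wall landmarks refines the result — three point pairs
cannot determine a 12-dof affine, so the similarity solution is the
honest closed form, with the full affine unlocked at >= 4 non-coplanar
pairs. Lesions in warped PET-like volumes are delineated at half the hot
spot's maximum and reduced to their intensity-weighted centroid; the
target registration error is the 3D Euclidean distance to the reference
centroid. Cohort summaries use Welch's unequal-variance t-test (the
safer default for an "unpaired t-test") and Pearson correlations.

## The synthetic phantom

No clinical accession accompanies the method, so validation runs on
seeded software phantoms: a hemispherical breast (default radius 50 mm,
2 mm voxels) of adipose tissue on a flat chest-wall slab; a
fibro-glandular compartment built as the superlevel set of a sum of
random anisotropic Gaussian blobs, thresholded at the exact quantile
that hits the target volumetric density (cohort medians 0.15 and 0.27
are presets; 0.15 is the default); a spherical lesion (5 mm radius) at a
configurable depth ratio; the nipple at the apex; three non-collinear
chest-wall landmarks. The CT-like channel has distinct tissue means with
sigma = 12 Gaussian noise — enough separation for two-class fuzzy
c-means to be exercised realistically; the PET-like channel is
near-uniform soft tissue with an 8x hot lesion, blurred at 4 mm FWHM
(a typical clinical PET kernel). The prone (MR-like) appearance is the
CT-like volume warped through a forward simulation at known ground-truth
moduli (default true adipose E = 2 kPa, within the range the inverse
method reports on patients).

The default radius (50 mm, a ~260 mL hemisphere) is the package's
desk-scale compromise: large enough for a realistic gravity number
(rho g R / mu ~ 0.7 at E = 2 kPa, i.e. genuinely large deformation, ~10
mm nipple sag) while keeping the full ladder-plus-inverse verification
in minutes on one core.

**What the phantom does not emulate:** Cooper's ligaments and tissue
anisotropy, pectoral muscle sliding, MR intensity characteristics (the
MR-like volume is warped CT by construction), PET physics beyond blur
and noise, posture differences beyond gravity reversal, and inter-visit
anatomical change. Ground truth and inverse search also share one
forward model (the classic inverse-crime setup), so passing recovery
tests demonstrates the estimator's correctness and identifiability, not
clinical accuracy of recovered moduli.

## Numerical choices and degenerate inputs

- Fuzzy c-means: fuzzifier 2.0, centroid-shift tolerance 1e-5 (relative
  to the intensity range), max 300 iterations, deterministic percentile
  initialisation (25th/75th for two classes); a voxel exactly on a
  centroid receives crisp membership. Cluster-to-tissue assignment by
  centroid order (fat is darker on CT).
- Resampling is trilinear on the node-centred grid convention
  `world = origin + index * spacing`; label maps resample with
  nearest-neighbour order.
- Crop boxes clamp to the image; no padding is invented.
- Meshing requires the element size to be at least the voxel spacing;
  empty masks, empty meshes and non-breast label maps raise.
- Skin extrusion offsets are scaled by the inverse mean cosine between
  node normal and adjacent facet normals so flat-face prisms keep the
  full thickness; offset nodes closer than thickness/4 merge (concave
  stair-step corners), with a warning.
- The element-inversion guard raises with the offending element ids;
  deformation gradients with J <= 0 are rejected everywhere.
- Landmark fits reject collinear triples; reflections are rejected only
  for genuinely chiral (>= 4 non-coplanar) correspondences — a mirrored
  coplanar triple is reachable by rotation and is fitted as such.

## Problem sizes used in the shipped verification

The test suite validates on hemispheres of 20-32 mm radius at 4 mm
elements (seconds per solve) and the acceptance script on the default
50 mm phantom: the 8/4/2 mm convergence ladder (~33k elements at 2 mm)
and the full inverse recovery at the 4 mm analysis mesh. These sizes are
the package's choice of desk-scale study conditions; all algorithms are
size-agnostic.

## Known limitations

- Quasi-static, isotropic, single-constituent tissues; no viscoelasticity
  and no contact (cases where the breast touches the coil are out of
  scope).
- The membrane skin carries no bending stiffness; sub-facet wrinkle
  geometry is homogenised away by the tension-field relaxation.
- At very soft moduli the wrinkling membrane admits nearby equilibrium
  branches (distinct wrinkle patterns, node positions ~1 mm apart): which
  branch a solve lands on depends on its starting point. The pipeline
  always proceeds by warm-started continuation, so its branch choice is
  internally consistent — the reference-state round trip is therefore
  defined (and verified) through the warm-started forward map the fixed
  point iterates.
- Extremely soft cold starts (E at the 0.5 kPa lower bound on large
  phantoms) can sit beyond a static stability limit of the ramped
  loading path and fail to converge; the grid search records such trials
  as failed and the stiffness continuation avoids the regime in
  practice.
- The voxel ("sugar-cube") mesh has a stair-step boundary; surface
  quantities converge with refinement but the staircase area itself does
  not tend to the smooth-surface area.
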