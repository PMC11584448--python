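# Methods

`breastfem` simulates the dynamic mechanics of the female breast during
running with a multi-component nonlinear finite-element model, and runs the
analyses that such a model supports: recovering the gravity-free reference
shape of a scanned breast, validating simulated motion against marker
trajectories and scanned surfaces, and quantifying how the stiffness of the
internal tissues moves the breast surface.  Because no subject scan data are
deposited anywhere we can reach, the package generates a parametric
synthetic anatomy with the documented tissue dimensions and a synthetic
clavicle trajectory with the documented sampling and cadence; everything
downstream is geometry-agnostic.

## Synthetic anatomy

The model is one (left) breast on a half torso, the sagittal plane being a
symmetry plane.  A graded rectilinear grid is laid over the torso footprint
(fine spacing inside the breast footprint, coarse outside), each cell is
split into the six Freudenthal tetrahedra — identical in every cell, so the
mesh is conforming — and the vertical coordinate of each grid column is
mapped from a curved chest-wall plate to the outer skin surface.  Tissue
components are labels on this one mesh, so every tissue interface shares
nodes ("glued" interfaces by construction):

* **chest wall**: a cylindrical plate (radius 200 mm) representing the rigid
  torso; its surface nodes form the driven `torso_base` set;
* **pectoralis major**: a slab on the wall, 12 mm thick at the centre
  tapering quadratically to 4 mm at the edges;
* **soft-tissue layer**: the 25 mm subcutaneous layer outside the breast
  footprint;
* **breast**: an ellipsoidal dome (default base radius 55 mm, protrusion
  45 mm) of adipose tissue containing
  * a **glandular sub-model**: 18 lobes (diameters drawn uniformly from
    15–18 mm) in a double circular array around the nipple axis (6 inner,
    12 outer; ring radii are the smallest that keep the lobes disjoint,
    scaled by 1.1), each joined by a tapering duct (4 → 2 mm) to a circular
    body behind the nipple;
  * **Cooper's ligaments**: a closed 3-D network of 8 radial septa (L1–L8,
    3 mm nominal thickness) plus an anterior sheet under the skin and a
    posterior sheet on the pectoralis covering the upper two thirds of the
    breast;
* **skin**: 1.5 mm triangular membrane shells over the outer surface.

Elements get their component by centroid location.  Sub-structures thinner
than an element (ducts, septa) are additionally captured along their
centerlines, and every lobe is guaranteed at least one element, so all
sub-structures remain addressable at desk-scale meshes (~3,000–15,000 tets
by default; element counts are configuration, not constants).  Two caveats
follow from this: the effective thickness of septa and sheets is bounded
below by roughly a third of the fine mesh size, and interfaces between
components are stair-stepped at element resolution.

A note on scaling: doubling only the breast radius does not scale the total
mesh volume by 8, because the soft-tissue layer and pectoralis keep their
absolute thicknesses; geometric similarity (all lengths doubled, see
`AnatomyParams.scaled`) does, and that is what the scaling test asserts.

The synthetic clavicle trajectory is sampled at 120 Hz: vertical
displacement `A_y sin(2 pi t / T)` with `T = 0.38 s` (one maximum and one
minimum per half gait cycle, the t2/t4 analogues), mediolateral sway at
half that frequency, optional Gaussian marker noise, and an optional
smooth amplitude ramp over the first half-cycle(s) so an undamped
simulation reaches near-steady cycling before the analysed window.
Defaults `A_y = 30 mm`, `A_x = 10 mm`, noise 0.5 mm emulate the vertical
torso excursion and marker jitter of treadmill running at ~6 km/h.  The
t1/t3 events (foot-off, foot-strike) cannot be detected from a clavicle
trace; they are defined as the mid-phase crossings of the vertical
waveform and documented as analogues.

What the generator does *not* emulate: subject-specific asymmetry, skin
pre-tension, breathing motion, scanner noise and holes, arm shadowing.
Passing tests on this anatomy show the pipeline is implemented correctly
and that the documented qualitative mechanics emerge; they do not certify
subject-specific displacement or stress magnitudes.

## Constitutive models

All tissues are isotropic, hyperelastic and nearly incompressible
(nu = 0.49).  The strain energy is decoupled into an isochoric part in the
barred invariants of the left Cauchy–Green tensor and a volumetric penalty:

* Neo-Hookean (skin, soft layer, pectoralis, ligaments, gland):
  `W = mu/2 (I1b - 3) + (1/d)(J - 1)^2`, `mu = E / 2(1+v)`,
  `d = 6(1-2v)/E`;
* five-parameter Mooney–Rivlin (adipose):
  `W = sum C_ij (I1b-3)^i (I2b-3)^j` over (i,j) in {10, 01, 11, 20, 02}
  with C10 = 0.31, C01 = 0.3, C11 = 2.25, C20 = 3.8, C02 = 4.72 kPa, plus
  the same volumetric penalty with `d` taken from the law's small-strain
  effective modulus `E_eff = 2 (1+v) * 2 (C10 + C01)` (≈ 3.6 kPa).  The
  published form of this material does not state its volumetric treatment
  or invariant convention; the decoupled (barred) convention is chosen and
  the choice matters only at volumetric strains the penalty suppresses.

Young's moduli: skin 500, ligaments 100, gland / soft layer / pectoralis
10 kPa.  Densities (kg/m^3): adipose 950, ligaments 1040, gland 1070,
pectoralis and soft layer 1050; skin density is not established by the
sources used here and defaults to 1050 (configurable).  Units are mm–kg–s,
in which stress is exactly kPa and densities convert by 1e-9; gravity is
9800 mm/s^2.

## Finite-element solver

Total-Lagrangian 4-node tetrahedra with one quadrature point.  The first
Piola–Kirchhoff stress is analytic; the consistent material tangent is
closed-form, verified in the test suite against a complex-step derivative
of the stress (exact to round-off) and against finite differences of the
assembled residual.  Newton's method carries a backtracking line search on
the residual norm, which carries the iteration through locally indefinite
states (the bending-free skin membrane wrinkles under compression near
peak load and briefly makes the tangent indefinite).

**Near-incompressibility.**  Constant-strain tetrahedra lock volumetrically
at nu = 0.49.  The solver therefore uses patch-based mean dilatation: the
six tetrahedra of each grid hex (split by component so a patch never mixes
materials) share the volume-averaged dilatation `theta = sum(J_e V_e) /
sum(V_e)` in the volumetric energy `(1/d)(theta-1)^2 V_patch`.  The tangent
is the element-local linearization at frozen patch pressure plus the exact
rank-one coupling `G_p^T (U''/V_p) G_p` per patch.  Meshes without patch
information fall back to per-element dilatation.  The hanging-block
refinement test demonstrates the effect: without patch averaging the tip
deflection did not converge under refinement; with it, a 2x-per-axis
refinement changes the answer by under 1%.

**Skin** is a membrane: thickness times an incompressible plane-stress
Neo-Hookean energy in the surface deformation gradient; no bending
stiffness.  This is a documented simplification — skin wrinkling is not
resolved.

**Boundary conditions.**  The torso-base node set is glued to the rigid
torso: its X and Y displacements follow the (filtered) clavicle trajectory
and Z is held at zero.  Prescribing base X motion while pinning the
sagittal plane at x = 0 would be contradictory, so the symmetry condition
is expressed in the torso frame: symmetry-plane x-DOFs carry the same X
trajectory as the base, i.e. the sagittal plane translates rigidly with the
torso, and the zero-normal-displacement invariant is measured relative to
that moving plane.  Gravity is applied to every deformable component by
default, with a per-component switch.

**Statics**: incremental gravity loading (default 4 increments, automatic
bisection on failure) with Newton–Raphson, converged at a residual below
1e-6 of the external force norm.

**Dynamics**: implicit Newmark, average acceleration (gamma = 1/2,
beta = 1/4, no numerical dissipation), time step 0.005 s, full
Newton–Raphson per step with automatic local step bisection (up to 4 cuts).
The initial state is the gravity equilibrium at rest.  Two numerical
choices deserve note:

* the 120 Hz trajectory is resampled to the solver grid with a cubic
  spline, and the velocity/acceleration of *prescribed* DOFs are computed
  by central differences of the known base motion rather than by the
  Newmark recursion — with a lumped (row-sum) mass matrix the prescribed
  rows are decoupled from the free equations, and the recursion's weakly
  stable (-1)^n mode would otherwise pollute reported accelerations and
  reaction work;
* within Newton, the factorized tangent is cached across iterations and
  time steps and refreshed whenever the residual reduction stalls (ratio
  above 0.33), which restores the quadratic tail near the solution; each
  step starts from the previous converged state because explicit
  displacement predictors overshoot the stiff modes of this system.

Optional mass-proportional Rayleigh damping exists as a robustness flag and
is off everywhere in the shipped tests and analyses.  Energy accounting
(discrete kinetic energy + strain energy vs gravity + support work,
trapezoidal quadrature) closes to a few parts per million over a
one-second undamped run driven by the noiseless waveform; with marker
noise on the drive, the trapezoidal quadrature of the support work over
the jittery prescribed path — not the integrator — accumulates a few
percent of apparent imbalance, which is why the energy audit uses the
smooth drive.

## Gravity-free reference configuration

Fixed-point iteration: initialize by deforming the observed (loaded)
geometry under reversed gravity, then repeatedly deform the current
reference under downward gravity and add the surface mismatch (times a
relaxation factor alpha, halved automatically if an update would invert
elements) to the reference coordinates.  The mismatch metric is the
maximum nodal distance over the breast-surface node set, because only the
scanned surface is observable; the published description of the procedure
states no tolerance, step factor or iteration cap, so tol = 0.1 mm,
alpha = 1 and max 30 iterations are exposed as settings.  The upward-
gravity solve is treated as the initializer only, not as part of every
iteration.  On the synthetic anatomy the initializer is already within a
few hundredths of a millimetre (the load is modest and the response nearly
linear), so the loop typically certifies convergence in one iteration;
the round-trip test recovers a known reference well inside 5x tolerance.

## Validation metrics

* **Zero-lag low-pass filtering**: a 2nd-order Butterworth applied forward
  and backward (effective 4th order, zero phase), cutoff 6 Hz applied
  directly — the common biomechanics convention; a flag applies the
  0.8022 double-pass cutoff correction instead.
* **RMAE**: mean over retained frames of |D_exp - D_sim| / |D_exp|.
  Frames with |D_exp| below eps = 0.5 mm are excluded (and counted) so the
  relative error stays defined; the printed form of the statistic leaves
  the prefactor/summation-limit mismatch ambiguous and it is implemented
  as the mean over retained samples.  Displacements are compared from each
  signal's first standing frame when the datum option is set.
* **Surface-to-surface distance**: for every simulated node in every
  frame, the exact nearest point on the reference triangulated surface
  (point-to-triangle, not point-to-vertex) via a provably sufficient
  KD-tree candidate set (vertex-distance upper bound plus maximum triangle
  circumradius), averaged over nodes and frames.  The printed definition
  of this statistic sums squared norms yet is reported in mm as an average
  Euclidean distance; the default here is the mean unsquared distance,
  with the squared variant available as a mode.  By default the average is
  restricted to the breast-surface node set.

## Experiments

Representative material points per component: the nipple node; the
ligament anterior sheet just behind the nipple; the glandular lobule
centroid; the pectoralis slab centre; the driven clavicle node.  Total
displacement is the Euclidean norm of the three components, measured from
the first (standing) frame.  Regional stress summaries are volume-weighted
mean von Mises histories over geometrically defined element sets (the 8
septa and 2 ligament sheets, anterior/posterior pectoralis halves, gland
front/top/rear/bottom quadrants, the adipose shell adjacent to the gland —
regions the source material marks only on figures, so they are defined
geometrically here).

Because the undamped response keeps a small free-oscillation component,
event-synchronous quantities are extracted as window peaks rather than
instantaneous samples: component displacements as the peak over the
analysed half-cycle (the "at maximum displacement" ordering), and the
sweep metric as the peak of nipple displacement within a quarter-cycle
window centred on each event (instantaneous sampling remains available).

The stiffness sweeps rerun the full static + dynamic pipeline over the
five-level Young's modulus grids (gland 5, 7.5, 10, 12.5, 15 kPa;
ligaments 80, 100, 120, 140, 160 kPa), all other materials held fixed,
read the nipple displacement at the t1..t4 events of a steady analysed
half-cycle, and fit displacement vs E per event by ordinary least squares
(slope in mm/kPa, Pearson r).  The default protocol simulates two half
cycles (0.76 s, 152 steps) with the amplitude ramped over the first and
analyses the second, at a ~2,600-tet mesh — sizes chosen so a full
two-component sweep is a coffee-break computation on one core.

A finding worth stating plainly: on this synthetic configuration the
stiffness sweeps show the expected negative displacement-vs-E slope at
the t4 analogue (the braking extremum, where effective load peaks) for
both components, but a zero-to-slightly-positive slope at the t2 analogue.
At t2 the base's downward acceleration (A omega^2, about 0.84 g at the
0.38 s half-cycle and 30 mm amplitude) cancels most of gravity, so the
displacement there is dominated by elastic sag recovery, which stiffer
tissue completes faster within the near-weightless window.  The behaviour
is robust across sampling functionals, ramp lengths and mesh resolutions,
and light damping only flattens it to zero; the corresponding acceptance
checks assert the subject-study property and therefore fail on the
synthetic anatomy, by design rather than by accident.

## Known limitations

* No contact (bra–skin, self-contact), no viscoelasticity, anisotropy or
  active muscle; the rigid torso is a driven node set, not a contact body.
* Linear tetrahedra with stair-stepped internal interfaces; stress
  concentrations at material interfaces are resolved only to element size.
* The undamped Newmark scheme keeps a small free-oscillation component
  superposed on the driven response; event-synchronous snapshots on the
  synthetic anatomy therefore carry a phase sensitivity that subject data
  (and dissipative commercial integrators) would not show to the same
  degree.
* Absolute displacement, acceleration and stress magnitudes depend on the
  unavailable subject geometry and motion; only their orderings, peak
  timings and trend signs are meaningful on the synthetic anatomy.
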