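# Methods

This note documents the models behind `gprspine`: what is computed, under
which assumptions, with which defaults, and where the desk-scale
simplifications end.

## Coordinate convention

Right-handed global frame: +Z cephalad, +X anterior, +Y patient-left. A
right thoracic curve therefore has its apex at negative Y relative to the
Central Sacral Vertical Line (CSVL, the vertical through the S1 centroid's
transverse coordinates). All public angles are degrees; internal work is in
radians; lengths are mm, forces N, moments N·mm.

## Analytic deformity measurement

A spine is 18 vertebral poses (S1…T1), each a centroid plus an orthonormal
frame. Two penalized natural-cubic smoothing splines y(z) and x(z)
(`scipy.interpolate.make_smoothing_spline`) are fitted through the coronal
and sagittal centroid coordinates. Two numerical choices matter:

* **Penalized splines, not FITPACK.** FITPACK smoothing splines select knots
  discretely, which makes the fitted curve — and hence any angle read off
  its derivatives — discontinuous in the data; observed jumps reached 2.4°
  for sub-millimetre input changes. The penalized formulation keeps every
  data site as a knot and depends continuously on data and penalty. The
  default penalty (λ = 100) keeps residuals on smooth spines below 0.1 mm;
  it is halved automatically until the maximum centroid residual is ≤ 3 mm.
* **Ghost-point padding.** Natural boundary conditions (zero end curvature)
  flatten the end tangents, biasing arcs that end at S1 or T1 by up to 2.3°
  at 60°. Each fit is therefore padded with two quadratically extrapolated
  ghost points per end, moving the boundary condition outside the measured
  range; single-arc closed-form errors drop below 0.5° across 10–60°.

**Cobb angles.** Side-change points are the zero crossings of the coronal
curvature y″(z). The regional apex is the extremum of |y − y_CSVL| inside
the region (thoracic searched over [z_T12, z_T1], lumbar over [z_S1,
z_T12]); the arc is delimited against each neighbouring arc at the point of
minimal |deviation| between apexes, and each bound is realized as the
tangent extremum inside the arc (curve ends serve as bounds where no
neighbouring arc exists). The angle is |atan y′(z_up) − atan y′(z_low)| —
the angle between the bound tangents, equal to the angle between their
perpendiculars. Tangent-extremum (argmax) bound selection is used instead of
nearest-curvature-root selection because the measured angle then varies
continuously when nearly equal roots merge or split. Regions with less than
2 mm lateral deviation report 0° and a flag (measurement floor). When a
deformed posture is re-measured, an `apex_hint` pins the apex search to the
arc nearest the reference apex, so an over-corrected mirror arc cannot
silently take over the measurement.

**Sagittal curves.** Kyphosis is the unsigned sagittal tangent-angle
difference between T1 and T12, lordosis between L1 and S1 (both
configurable). The levels are a package choice: the cohort's printed
lordosis mean of 70° is only consistent with an S1-inclusive definition.

**Apical axial rotation.** The local anterior axis is projected onto the
transverse plane and compared with global +X; positive toward the patient's
right; degenerate (near-vertical) anterior axes raise an error.

## Synthetic cohort generator

The generator emulates the study cohort: right thoracic-major (or double
major with right thoracic component) adolescent spines. Parameters are drawn
from hard-truncated normals with the documented moments — thoracic Cobb
33° ± 9° on [11°, 45°], lumbar Cobb mean 27° on [13°, 42°], kyphosis mean
30° on [10°, 47°], lordosis mean 70° on [57°, 85°], apical rotation
11° ± 9° on [−6°, 22°]; where only mean and range are documented, sd =
range/4. Note that truncation shifts the realized means (e.g. apical
rotation to 9.7°, thoracic Cobb to 31.6°); recovery tests compare against
the truncated-normal means.

Geometry template: S1 at the origin; 17 segment lengths linearly decreasing
38 → 22 mm cephalad, applied as *arclengths* — positions are integrated
along unit tangents so consecutive spacing stays at its template value
regardless of how steep the drawn curvatures are. The coronal deviation
profile is a chain of smoothstep pieces (0 → +D_l at the lumbar apex → 0 at
the arc crossing near the thoracolumbar junction → −D_t at the thoracic apex
→ 0 below T1), whose piecewise tangent extrema make the two Cobb angles
nearly decoupled functions of the two amplitudes. The sagittal tangent-angle
profile is a lordotic decay (S1 → L1) plus a kyphotic rise (T12 → T1) plus a
balance constant solved so T1 stands over S1. Amplitudes are iterated
(damped multiplicative updates, ≤ 50 iterations) until the *measured*
indices match the drawn ones (0.5° / 1° internally; the documented contract
is 1° Cobb, 2° sagittal). Axial rotations are assigned per level
proportionally to the local lateral deviation, peaking at the drawn value at
the thoracic apex; frames are pure axial rotations (no measurement consumes
a tangent tilt). Vertebral masses and heights are template defaults; the
cohort description carries no per-patient anthropometry.

**Apex feasibility.** Because adjacent arcs share flank tangents, a large
curve adjacent to a small one puts a floor on the small curve's measurable
angle; strongly lumbar-dominant draws with adjacent apexes (e.g. θ_L = 32°,
θ_T = 13°, apexes L1/T9) are geometrically unrealizable. The apex pair is
therefore drawn uniformly among the *feasible* combinations of
{T7, T8, T9} × {L1, L2, L3} for the drawn angles, and θ_L is redrawn when no
pair is feasible — mirroring the cohort's right-thoracic-major inclusion
criteria. With this rule the generator converged on 2000 consecutive draws.

**Self-correction targets.** Targets are transverse (x, y) positions for
T1 and the two apical vertebrae. The thoracic arc of the reference shape is
flattened proportionally toward the CSVL (factor γ, smoothstep-blended in
from zero at the lumbar apex) until the flattened shape re-measures at the
requested reduction fraction (solved by Brent's method; within 3 percentage
points by construction); T1 is pulled onto the CSVL (proportionally for
fractions below the cohort-average 0.33); the lumbar apex stays at its
reference position (the lumbar curve remained constant in the study).
Sagittal targets reduce kyphosis and lordosis by 6° and 5° scaled by
fraction/0.33, via a reduced tangent-angle profile re-integrated and
anchored at the lumbar apex. Negative fractions (down to −0.2) emulate
patients whose curve increased.

## Trunk finite-element model

Rigid vertebrae are nodes with 6 dof; each intervertebral joint is a 3D
Timoshenko beam element whose section properties map functional-spinal-unit
(FSU) stiffnesses onto an equivalent prismatic beam of the segment length L:
EA = k_ax·L, GAs = k_sh·L, GJ = k_tor·L, EI = k_bend·L (so that, e.g., pure
bending gives M = k_bend·Δθ across the joint). Local element frames take
bending about the anterior-projected axis as lateral bending (k_lb) and the
orthogonal axis as flexion-extension (k_fe).

Defaults (configurable): k_ax = 800 N/mm, k_sh = 150 N/mm,
k_lb = k_fe = 1.5·10⁵ N·mm/rad (≈ 2.6 N·m/deg), k_tor = 2.5·10⁵ N·mm/rad —
order-of-magnitude values from published FSU data. The rib cage, costal
cartilage and sternum are collapsed into a ×1.5 stiffening factor on the
thoracic segments (upper node T12…T1). A global scale s multiplies all
stiffnesses and stands in for the unpersonalized overall trunk rigidity.

The analysis is linear and incremental about the imaged standing posture,
which already includes gravity; gravity loads therefore default off for
correction simulations, with `apply_gravity` available for exploratory load
cases (per-level fractions: T1 carries 0.13 for head + arms, each of T2–L5
carries 0.02; total 0.45 of body mass above the pelvis; g = 9.81 m/s²).
Constraints are handled by dof elimination (partitioned solve), giving exact
prescribed values and clean reactions; S1 is always fully fixed. The solver
checks symmetry, the equilibrium residual (< 10⁻⁶ of the load scale) and
global force balance.

**Calibration.** `calibrate_global_scale` bisects s (in log space) until the
cohort-mean simulated manual-correction reduction matches a target within
0.02 percentage points. Two numerical points: (i) the search first scans
stiff-to-soft to bracket the crossing, because reduction is not monotone to
the soft limit — an over-soft model over-corrects past straight and the
unsigned Cobb rises again; (ii) linearity is exploited, u(s) = u_force/s +
u_righting, so each probe re-measures cached solves instead of refactorizing.

## Correction simulations

**Manual correction.** The therapist's equivalent force (default 31 N,
purely lateral +Y — an anteroposterior component is not documented and
defaults off) acts at the thoracic apical node; the pelvis is fixed; T1 may
slide vertically but is held at its reference sagittal position and on the
CSVL coronally (a stand-in for the righting reflex), rotations free. The
skin-to-vertebra load path is not modelled: the force acts at the vertebral
node itself, consistent with the index definition.

**Self-correction.** Transverse (x and y) positions of T1 and both apical
vertebrae are prescribed at their targets; Z and all rotations stay free; no
external loads. The reported reaction R is the Euclidean norm of the
transverse reaction at the thoracic apex node.

**Stiffness index.** SI = F/Δθ_T (manual) or R/Δθ_T (self), with Δθ_T =
θ_T(before) − θ_T(after), positive for a reduction. The index is flagged
undefined below a 0.25° reduction; negative raw values (curve increase) are
carried through flagged, matching the study's printed −0.40 row. Table-style
reports round half away from zero.

Because the angle re-measurement (spline fit + arctangent) is nonlinear in
the displacement field, SI is only approximately force-invariant: measured
spread ≈ 3.5% over 10–60 N at default stiffness, while the displacement
field itself scales exactly. Similarly, the self-correction simulation does
*not* reproduce the target-shape reduction: with FSU-level shear compliance
the localization length √(k_lb/k_sh) ≈ 32 mm — one segment — so prescribed
displacements at three vertebrae deform the spine locally and the simulated
reduction tracks roughly 40–50% of the target fraction (the original
patient-specific study also underestimated: simulated 25% vs actual 33%
mean). What the simulation does preserve, and what the tests assert, is the
monotone coupling between requested and simulated reduction (cohort
correlation ≈ 0.9), strictly positive apex reactions of realistic magnitude
(cohort mean ≈ 45 N), and exact attainment of the prescribed positions.

## Study statistics

The 16-patient result tables are packaged as CSV fixtures (decimal comma
"−0,40" normalized at build time). `summarize` reproduces the
"mean ± sd [min–max]" rows (sample sd, n−1); `pearson` the correlations;
`recompute_stiffness_indices` recomputes each row's index from the printed
force and Cobb pair and flags rows where the printed index was evidently
derived from unrounded study values (e.g. the patient whose printed Cobb
change is 0° yet whose index prints 21 N/°). Two printed correlations
(force vs reduction, manual vs self) are reported but not asserted: the
study computed them on unrounded internal values (pressure rather than
force for the first), and the printed columns yield 0.58 and 0.07. The
original ANOVA + post-hoc Tukey comparisons are deliberately not
reimplemented; the report carries plain paired mean differences with sds.

Synthetic mode chains the whole pipeline: generate a cohort, calibrate s to
the fixture-table mean manual reduction (26% at 31 N), simulate the manual
correction for every patient, draw per-patient self-correction fractions
from the actual-correction distribution (mean 33%, sd 20%, range [−15%,
69%]), construct targets and simulate; everything is deterministic under a
single seed.

## What passing tests do and do not show

The synthetic cohort reproduces the documented marginal distributions of the
deformity indices and a plausible spine geometry, but not real radiographic
reconstructions: no vertebral shape, no pedicles, no per-patient
anthropometry, no measurement noise, and axial rotation is geometric
bookkeeping that does not enter the stiffness model. The FEM is linear,
desk-scale and calibrated at cohort level; per-patient agreement with
patient-specific nonlinear models built from radiographs is out of scope and
not claimed. Problem sizes used throughout (n = 16 study runs, n = 200
distribution checks, 50-draw measurement loops) were chosen as the smallest
that exercise the claims.
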