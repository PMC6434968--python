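# Methods

Units throughout: lengths mm, conductivities S/m, currents mA at the API
(A internally in the solver), potentials V (mV at the axon membrane),
times ms in the axon model and us in the safety arithmetic, areas mm^2,
charge uC, charge density uC/cm^2.

## Geometry

The cord segment is an 80 mm axial extrusion of a layered cross-section
(x lateral, y dorsoventral, z axial):

* white matter: ellipse, semi-axes 4.0 x 3.25 mm;
* gray matter: butterfly built from a central commissure ellipse and four
  tilted horn ellipses (union of convex pieces);
* CSF / inner dura: 8.0 x 5.5 mm outline whose dorsal half is a
  superellipse (exponent 4), i.e. locally flattened where the electrode
  plate is clamped — this keeps the flat, coplanar electrode sites inside
  the CSF space without staircase artifacts;
* dura + extradural fat: a merged 1.0 mm shell; its outer surface and the
  axial end caps are the grounded return boundary.

Conductivities: gray 0.23; white anisotropic 0.6 longitudinal / 0.083
radial (tensor axes aligned with the grid); CSF 1.7 (about 20x the radial
white value, the source of the strong CSF current shunting); shell 0.04.

The 12-site T-array lies on the underside of an insulating substrate whose
bottom face protrudes 0.3 mm below the flattened dura: a 6-site cross row
(1.35 mm pitch; the innermost pair are the central-site CS group, the outer
four the traverse TS group whose extreme pair are the "tips") and a 6-site
stem column (1.65 mm pitch, starting 1.95 mm caudal, the base BS group).
Every site is 1.2 x 1.4333 mm = 1.72 mm^2.

## Field solver

Cell-centered finite volumes on a nonuniform rectilinear grid. Grid lines
are snapped to every site edge and to the plate level, so site facet areas
are exact (1.72 mm^2 to round-off at every resolution). Face conductances
are harmonic (series half-cell) combinations, which treats both the
anisotropic white matter and all layer interfaces exactly in the two-point
flux sense. Electrode sites are perfect-conductor supernodes with a
prescribed total current (terminal constraint): one extra unknown per site
enforces equipotentiality while the current distribution over the metal is
free, concentrating at the site edges as expected; inactive sites float
with zero net current. The resulting symmetric system is factorized once
(sparse LU) and back-solved for the 12 unit-current (1 mA) basis fields.
An iterative conjugate-gradient path was evaluated and rejected: the
conductance contrast between metal supernodes and the resistive shell
leaves ILU-preconditioned CG stalled, while the direct factorization of
the ~100k-cell default mesh (0.35 mm nominal spacing, graded outward)
takes under a minute and ~2 GB.

Any montage field is a superposition of basis fields; the mutual-resistance
matrix R (site voltage per site ampere) gives power as I^T R I. R is
symmetric to solver round-off (reciprocity of the symmetric operator) and
positive definite (passivity). A boundary-current audit sums ground-face
currents per tag (outer shell vs end caps); the conservation mismatch is at
solver round-off. The fraction of delivered current entering the white
matter is the sum of positive inward normal currents over white/CSF and
white/gray interface faces divided by the total cathodic current.

## Axon model

Single-cable myelinated axon: 21 nodes of Ranvier joined by perfectly
insulated internodal axoplasm (resistivity 70 ohm cm). Node membranes carry
fast Na, persistent Na, slow K and linear leak conductances with mammalian
kinetics at 36 C (standard MRG-class rate functions), cm = 2 uF/cm^2,
E_Na = 50 mV, E_K = -90 mV; the leak reversal is solved so that -80 mV is
an exact resting equilibrium. Fiber classes (diameter, node spacing, node
diameter, internodal axon diameter, um): (7.3, 750, 2.4, 4.6),
(11.5, 1250, 3.7, 8.1), (15, 1450, 5.0, 10.4).

The extracellular potential sampled at the node positions enters the cable
equation through second spatial differences (the activating function),
with sealed ends; a spatially constant potential cannot excite the fiber,
and a linear ramp can excite only the terminal nodes (the end-node effect:
the discrete cable amplifies the end step by roughly sqrt(Ga/Gm) ~ 8x, so
even modest uniform gradients recruit the sealed ends — an artifact of the
abrupt 21-node termination, not of the interior cable).
Stimulation is a 200 us rectangular cathodic phase; a fiber is *activated*
when any node crosses +5 mV absolute within 1 ms.

Two integrators: an adaptive RK45 reference path (rtol 1e-6, atol 1e-8,
terminal +5 mV crossing event) and a numba-compiled fixed-step RK4 batch
engine (dt = 1 us) with linearly interpolated rate tables that advances
thousands of independent fibers at once; the two agree on thresholds to
well under 2%. Thresholds are found by doubling-bracket bisection to 1%.

## Activation mapping

A 0.1 mm grid covers the cord cross-section. At each white-matter point an
axially oriented fiber of each class is centered under the array and
integrated to a binary outcome; points are labeled by recruitment breadth
(all sizes / medial and large / large only / none); the label is the
breadth implied by the smallest recruited class. Recruitment is monotone
in diameter for the smooth fields at the cord up to marginal grid points
(the classes sample the field at different node spacings, which can flip a
borderline outcome), which the scanner exploits (smallest class first,
short-circuiting the larger classes); a brute-force oracle without the
short-circuit validates the labels. Gray-matter points
carry the off-target constraint and are evaluated with the largest
(lowest-threshold) class only. Recruitment depth is measured below the
local dorsal white-matter surface within a 2 mm-wide midline column.

## Steering sweeps and calibration

Depth schedule (9 trials): both CS sites are cathodes; the anodic return
shifts linearly from the two tips (trial 1) to the six stem sites
(trial 9). Lateral schedule: linear blend from a lateralized tip-cathode
montage to the symmetric centered montage. Each trial is normalized to
1 mA total cathodic current, then calibrated by bisection to the largest
amplitude at which no gray-matter point activates (the field is linear in
amplitude, so the unit-field node potentials are rescaled inside the
bisection). Per-trial outputs: calibrated amplitude, power, per-class
recruited areas, recruitment depth and a per-site charge-safety report.

The summary figures are: the white-matter inflow percentage of a 4 mA
max-depth montage; the power ratio of trial 1 to trial 9; the power saving
of the last trial whose three class areas stay within 5% of trial 1's; and
the midline recruitment depth when the max-depth montage is scaled so the
most-loaded site sits at the 0.86 uC per-phase charge limit (4.3 mA for a
200 us phase). The only randomized degree of freedom is the axial node
alignment of the fibers (uniform within one internode, seeded); reported
values are replicate means.

## Safety arithmetic

Per-site phase charge |I| x 200 us against the 50 uC/cm^2 platinum limit
on 1.72 mm^2 (0.86 uC, hence 4.3 mA per site at 200 us); tissue exposure
J x t against 30 uC/cm^2; biphasic waveforms must balance charge exactly
(default recovery: quarter amplitude, four-fold duration). An audit helper
also checks that the recovery phase alone recruits nothing.

## Known limitations

* The voxelized curved interfaces leave a small staircase error; region
  volumes converge to the analytic values within ~1% at the default mesh.
* The white-matter inflow fraction is sensitive to the idealized dorsal
  CSF gap and converges noisily (~4.5 +/- 0.2% for the max-depth montage
  across 0.5-0.3 mm meshes).
* Internodes are perfectly insulating (single-cable); paranodal/double-
  cable effects are not modeled. The resulting electrotonic length (~8
  internodes) is comparable to the 21-node fiber's half-length, so a
  recruited fiber fires near-synchronously: recruitment thresholds are
  meaningful, conduction timing is not.
* Axons are strictly axial; dorsal-root and curved-fiber trajectories are
  out of scope.
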