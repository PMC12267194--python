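# Methods

This note documents the models implemented in `aortaflow`, the conventions
and defaults behind them, and what the synthetic setting does and does not
establish about real patient data.

## Synthetic aortic population

Real studies of aortic morphology start from segmented CT surfaces brought
into point correspondence by non-rigid registration. `aortaflow` replaces
that acquisition chain with a generative model whose correspondence holds
by construction: every subject is a swept-tube surface built on a fixed
(ring, sample) layout, so the i-th point always sits at the same parametric
location and PCA can be applied directly. The ground-truth centerline and
inscribed radii are stored with each subject, which makes every downstream
stage testable against exact references.

The main vessel is an ascending straight segment, a circular-arc arch with
an out-of-plane sinusoidal displacement (the "torsion amplitude"), and a
straight descending segment; the lumen radius tapers linearly from the root
to `taper_ratio` × root radius. Three branch tubes (BCA, LCCA, LSA) attach
at arc-length fractions of the arch; the bovine-arch variant gives BCA and
LCCA a shared origin. Default parameter means describe an average adult
thoracic aorta — ascending tract ≈ 90 mm, arch tract ≈ 38 mm, descending
tract ≈ 124 mm, root radius 16 mm tapering to ≈ 11.7 mm, branch radii
6.3 / 3.4 / 5.3 mm — and per-field coefficients of variation of 5–8%
(30% for the torsion amplitude, whose anatomical variability is large).
The bovine-arch prevalence defaults to 0.2, at the upper end of reported
clinical frequencies, so the variant is exercised in cohorts of ~19.
Parameters are drawn from truncated normals at ±3 CV; the truncation
guarantees that every draw satisfies the anatomy invariants (positive
lengths and radii, ordered branch origins, arch angle in (π/2, 3π/2))
without rejection sampling, at the cost of slightly lighter tails.

The default resolution — 760 main rings + 3 × 80 branch rings × 25 samples
= 25,000 surface points — matches the node budget of typical corresponded
aortic meshes; all ring counts are configurable and tests use coarser
sweeps.

What the generator does *not* emulate: segmentation noise, registration
error (correspondence is exact here), non-circular lumen cross-sections,
wall thickness, and pathological remodeling. Passing tests therefore
demonstrate correctness of the algorithms on the swept-tube geometry class,
not robustness to imaging artifacts.

## Shape model

PCA uses the sample covariance with divisor n − 1, computed through the SVD
of the centered shape matrix. Mode signs are fixed by making each mode's
largest-magnitude loading positive, so generated-shape labels are
reproducible across runs and platforms. A centered PCA on n subjects has at
most n − 1 non-trivial components; `fit_pca` defaults to that, but the
pipeline fits a fixed-size mode book of n modes (the last carrying ~zero
variance) so that the default augmentation scheme — modes 0–4 swept over
{−3,−2,−1,+1,+2,+3} SD, modes 5–7 over {−3,+3}, modes 8+ over {+3} —
produces 47 novel shapes plus the template on a 19-subject cohort. The
scheme is a configurable table; the default concentrates shapes on early
modes because later modes each explain well under 1% of the variance and
a unit-step sweep there changes geometry imperceptibly.

SSM-generated shapes inherit the canonical mean-anatomy ring layout
(non-bovine branch origins), and their centerlines are recovered by the
ring-centroid rule rather than re-deriving topology per shape.

## Morphometry

The centerline point of a ring is the centroid of its surface samples, and
the inscribed-sphere radius is the minimum centroid-to-sample distance —
exact for circular rings and equal to the semi-minor axis for elliptical
ones. This replaces Voronoi-based maximal-inscribed-sphere extraction,
which would be needed for arbitrary surfaces but is superfluous on the
swept-tube class.

Tract boundaries sit at the branch ostia on the main centerline: ascending
= root → BCA, arch = BCA → LSA, descending = LSA → outlet, giving seven
tracts with the three aortic ones partitioning the total exactly. For a
bovine arch the ascending/arch boundary is the shared BCA–LCCA ostium.

Curvature κ = |r′×r″|/|r′|³ and torsion τ = (r′×r″)·r‴/|r′×r″|² are
evaluated with arc-length-parameterized central differences after a
moving-average smoothing (window 5 points, configurable; recorded in
output metadata). Discrete third differences amplify noise, hence the
smoothing; it is applied to curvature/torsion only, never to lengths or
radii. Torsion is set to zero where κ < 10⁻⁶ mm⁻¹, since the osculating
plane is undefined on straight segments, and is reported as a signed mean
plus SD. Tortuosity is length over endpoint chord and is clamped at 1 from
below only within floating-point roundoff (the triangle inequality makes
values < 1 impossible mathematically).

Representative selection ranks shapes by the maximum absolute percent
deviation from the template over all (tract, quantity) cells, restricted to
shapes generated from modes below the mode limit (default 10, k = 20).
"Most morphologically deviant" admits many formalizations; max-|%| was
chosen because it is scale-free across quantities with different units and
deterministic (ties broken lexicographically by label).

Result planes are placed at 85% of the ascending tract (pre-arch), 10%
(post-arch) and 90% (descending) of the descending tract, with the local
Frenet tangent as plane normal.

## Hemodynamics

The full incompressible Navier–Stokes problem is deliberately replaced by
a reduced-order analogue: a resistive network with Windkessel outlets, and
1D scalar transport for the ECMO fraction. The Windkessel relation and the
cycle-mean flow definition are implemented exactly; all claims tied to 3D
fields (local velocity, total-pressure extremes, streamline topology) are
outside this model's reach and are treated only as ordering or band
properties.

* **Segments.** Each aortic inter-ostia interval and each branch becomes a
  Poiseuille resistance R = 8μL/(πr⁴) with the tract's length and mean
  inscribed radius. Blood: ρ = 1060 kg/m³, μ = 3.5×10⁻³ Pa·s (dynamic
  viscosity; Poiseuille resistance is dimensionally consistent only with
  the dynamic value). A bovine arch collapses the BCA–LCCA interval to a
  point; its resistance uses a 0.5 mm shared-trunk length floor to keep the
  junctions distinct and the system well conditioned.
* **Outlets.** Three-element Windkessel per outlet, stepped implicitly
  inside the network solve; the standalone stepper uses the exact
  exponential update, which reproduces the convolution solution for
  piecewise-constant inflow. Calibration sets the total resistance from the
  band-center pressure over the cardiac mean flow, splits it per outlet by
  the target fractions (defaults 70/15/7.5/7.5% for descending/BCA/LCCA/
  LSA), fixes R_p/(R_p+R_d) = 0.1 and τ = R_d C = 1.5 s, then runs at most
  20 deterministic fixed-point passes until the measured cycle-mean splits
  are within 1% and the peak root pressure lies in the 120–130 mmHg band.
  The split fractions, R_p fraction and τ are package conventions from
  standard Windkessel practice — the underlying physiology fixes none of
  them uniquely — and are recorded in the run outputs.
* **Inflow.** The cardiac waveform is a rectified two-term sinusoid
  (ejection over 35% of the 0.8 s cycle, zero diastolic inflow), scaled
  multiplicatively to an exact cycle mean: 5 L/min healthy, 70% reduction
  (1.5 L/min) for cardiogenic shock. The waveform is a swappable asset.
* **ECMO topology.** Shock-mode networks append an abdominal segment
  (150 mm, distal descending radius) with its own outlet below the ECMO
  entry point, and the entry becomes a pure flow source. Without that
  distal outlet, all ECMO flow would be forced cephalad. The same topology
  is used for every EF level including 0, so mean outlet flows are exactly
  affine in EF and comparisons across support levels stay within one
  circuit.
* **Time stepping.** 1 ms implicit-Euler steps, three cycles, analysis on
  the final cycle to shed transients; the interior network stores no
  volume, so the instantaneous sum of outlet boundary flows equals the
  imposed inflow to solver precision at every step.
* **Transport.** The ECMO fraction φ ∈ [0, 1] (0 = native blood, 1 = pump
  blood) obeys conservative first-order upwind advection on a 240-cell
  axial grid with velocity Q(s,t)/A(s); native blood enters at the root,
  pump blood at the descending entry, and branch uptake removes fluid at
  the ostium cell's fraction. The scheme sub-steps automatically when the
  CFL number exceeds 1. First-order upwinding smears the native/ECMO
  interface over a few cells; front *position* is accurate (verified
  against particle tracking) while interface *sharpness* is not a
  prediction of this model.
* **Watershed.** The watershed position s\* is the most proximal axial
  location where the net flow changes sign at the queried instant (systolic
  peak = maximum cardiac inflow of the final cycle; diastole = minimum),
  classified against the ostia positions into ascending / BCA–LCCA /
  LCCA–LSA / at-LSA / descending / none. In a purely resistive network the
  instantaneous systolic jet can keep the whole aorta antegrade (zone
  "none") even when the cycle-averaged balance is retrograde; blood inertia
  — not modeled here — is what sustains a mid-aortic systolic interface in
  3D. The orderings that survive the reduction (higher EF ⇒ watershed at
  least as proximal; diastole at least as proximal as systole) are the
  quantities this package asserts.

## Pipeline conventions

A single global seed fans out to per-stage seeds through a fixed counter
scheme, so stages can be rerun in isolation. Windkessels are calibrated
once, on the template, and reused for every geometry: recalibrating each
anatomy to identical splits would cancel exactly the morphology-driven
flow differences the study measures. The healthy stage simulates the
selected 20 shapes plus the template; the ECMO stage takes the 4 shapes
with the largest absolute LCCA cycle-mean-flow deviation from the template
(the most flow-sensitive branch) plus the template, at EF = 0, 4 and
6 L/min. All pressures are reported in mmHg and flows in L/min
(1 mmHg = 133.322 Pa); SI units are used internally.

Default problem sizes (25,000 surface points, 240 transport cells, 2,400
timesteps per run) keep a full study under a minute on one core while the
discretization errors stay well below the tolerances asserted in the test
suite; tests use coarser geometry where only topology matters.

## Known limitations

* No blood inertia or vessel compliance inside the network (only in the
  outlets), hence no wave propagation and an instantaneous systolic
  watershed that is more distal than a 3D model would predict.
* No abdominal/iliac anatomy beyond a lumped extension; cannulation-site
  fluid dynamics are out of scope.
* Morphometric values are exact for swept tubes; on real segmented
  surfaces the ring-centroid centerline does not apply.
* Oxygen transport/saturation physiology is not modeled; φ is a pure
  advected mixing fraction.
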