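# Methods

This note documents the models implemented in `eelflume`, the assumptions
behind them, the defaults and why they were chosen, and what the
synthetic-data generators do and do not emulate.

## Coordinate convention and units

All internal coordinates are SI meters in a right-handed flume frame:
x streamwise with upstream positive, y lateral, z upward from the sand
bed, origin at the eel's burrow. The free stream moves downstream, i.e.
with velocity (−U, 0, 0). File readers accept a `cm` units flag and
convert on read; everything downstream is meters and seconds. Video runs
at 60 frames s⁻¹ by default.

## DLT camera model

Each camera is the classic 11-parameter direct linear transformation.
Calibration stacks two linear equations per correspondence and solves the
11-coefficient system by least squares; it refuses fewer than six points
or a coplanar/collinear point cloud (rank test on the centered 3D points),
because the system is then rank-deficient and the solution meaningless.
Triangulation likewise stacks two equations per camera,
`(L1 − u L9)X + (L2 − u L10)Y + (L3 − u L11)Z = u − L4` and the v
analogue, and solves for (X, Y, Z). No nonlinear refinement is applied:
at flume working distances (<1.5 m) and sub-pixel noise the linear
solution is accurate to well under a millimeter, which is an order of
magnitude below the body-point spacing being measured.

Numerical choices:

* The triangulation residual is the RMS over cameras of the per-camera
  reprojection distance (px).
* A result is flagged ill-conditioned when the row-normalized design
  matrix has condition number > 1e6 — in practice this fires only for
  camera baselines below ~10 µm at flume scale, i.e. effectively
  duplicate views.
* The projective denominator must exceed 1e-12; otherwise the point lies
  on the camera's focal plane and projection raises.
* Observations with pose-estimation confidence below 0.6 (configurable)
  are dropped before triangulation; a (frame, label) left with fewer than
  two views is skipped rather than guessed.

## Strike kinematics and reactive distance

A strike is an annotated open-mouthed lunge: initiation and capture
times with the eye positions at both, plus the prey capture point.
Derived metrics: strike time t = t_capture − t_init; strike distance
|Δeye|; earth-frame speed = distance/time; water-frame speed
|Δeye − (−U t, 0, 0)|/t. The water-frame speed matters because a strike
directed upstream does more work against the water than the earth-frame
displacement suggests.

Reactive distance assumes the prey is a passive tracer drifting
downstream at the flow speed (brine-shrimp nauplii are poor swimmers), so
its position at initiation is the capture point displaced upstream by
U·t; the metric is the eye-to-prey distance at that instant. At U = 0 it
reduces exactly to strike distance.

Strike endpoints normally come from annotations. A speed-threshold
detector (point speed > 3× its rolling median for ≥3 consecutive frames)
is provided as convenience plumbing for unannotated tracks; it is a
heuristic, not part of the measurement model.

## VeDBA

Per axis, the instantaneous acceleration at frame i is the three-point
second difference (p_i − 2 p_{i+1} + p_{i+2})·fps² — the second-order-
accurate central estimate at frame i+1, recorded at index i, so the
series is two frames shorter than the track. VeDBA is the per-frame
Euclidean norm of the three axes and the summary statistic is its
temporal mean. Because the stencil annihilates affine trends, VeDBA is
exactly invariant to constant-velocity drift, which is the property that
makes it a usable energy-expenditure proxy on position tracks. A
four-point one-sided stencil is an alternative reading of
"second-order forward"; at 60 Hz the two differ negligibly
(O((ω/fps)²) for body motion below a few Hz), and the three-point form
was chosen for its symmetry and lower noise amplification. Tracks with
frame gaps error by default; an opt-in mode fills gaps by linear
interpolation and flags the result, since interpolation suppresses
acceleration inside the gap.

The body point used for VeDBA is the first dark body spot when present
(closest clearly visible point to the body center), else the eye with a
logged warning.

## Body length and its third quartile

Length out of burrow is the arc length of the ordered body polyline from
the burrow origin to the snout; it requires a multi-point polyline (a
2-point eye+spot track has no meaningful arc length and is refused).
The feeding-model radius is the third quartile (Q3) of the per-frame
length series — between the mean (which under-covers the swept area) and
the maximum (which over-covers it). Quantiles use linear interpolation
between order statistics (position h = (n−1)p + 1), the common default;
the convention only matters for very short series.

## Segmented-cylinder drag

The posture polyline is split into 7–8 segments, each a circular cylinder
of diameter d = 0.005 m. Only the flow component normal to a segment's
axis generates drag (cross-flow principle; skin friction of the parallel
component is neglected, standard for slender bodies): U_n = U sin θ,
Re = U_n d/ν, F = ½ ρ_w Cd(Re) (d l) U_n². The default correlation
Cd = 1 + 10 Re^(−2/3) is a smooth-cylinder subcritical fit, valid for
Re < 2e5 (a warning fires above); it is isolated behind one function and
replaceable by any callable. Fluid defaults are seawater at 25 °C:
ρ_w = 1025 kg m⁻³, ν = 9.7e-7 m² s⁻¹.

The whole-body drag coefficient uses reference area d × total arc length,
which makes an 8-segment straight perpendicular body reproduce the
single-cylinder Cd exactly (a projected-frontal-area alternative would
not have this property). At U = 0 the force is zero and Cd is undefined;
the result carries an explicit flag instead of a number.

Arc-length-uniform resampling places new vertices on the polyline at
equal arc spacing. Chord lengths between such vertices under-count the
body length at corners, so each resampled segment carries the arc length
of its polyline portion (total/n) as its cylinder length while its axis
is the chord direction. This conserves total body length exactly and
reduces to plain chords for straight bodies; the small angle smoothing it
introduces is second-order in the bend per segment.

Counterfactual scenarios: (1) `fixed_posture_and_length` evaluates the
low-flow geometry unchanged at the high flow speed — what drag would cost
had the eel not responded; (2) `shortened_straight` builds a straight
body at the observed high-flow length. The straight body's orientation is
vertical by default (the limit posture of an unbent anchored eel); a
`mean_axis` option uses the low-flow body's chord instead, since the
choice is genuinely open.

## Foraging models and trial bookkeeping

The disk equation F = aρ/(1 + aρh) covers the density-dependence;
at the densities of interest the response is nearly linear (h small), so
the least-squares fit of (a, h), bounded at zero, reports a handling time
that is weakly identified — expected, and left visible rather than
regularized away.

The prey-flux model treats the eel as capturing every prey crossing a
semicircular area of radius L = Q3(length out of burrow) in the
cross-flow (y–z) plane, flat side on the bed:
F = 60 ρ U πL²/2 prey min⁻¹. The semicircle's plane is stated explicitly
here because only the schematic implies it; the π/2 constant is exact.

Trial bookkeeping mirrors a recirculating flume: trial duration is one
water cycle = circuit length / U. The circuit length (5.6 m by default)
is anchored by an observed pair — two trials at 0.10 m s⁻¹ spanning 6720
frames at 60 Hz — and frame counts at other speeds follow as
n·fps·circuit/U, rounded half-to-even (4480, 3360, 2688 at 0.15, 0.20,
0.25 m s⁻¹). Released prey = round(ρ × 1.24 m³). Captures = released −
recovered − (mean control loss fraction × released); control losses in
empty-flume runs are ≤5%, and a corrected capture count that goes
negative clamps to zero with a warning, since the correction is a mean
while single-trial losses fluctuate. Rates divide by the cycle time in
minutes.

## Synthetic scenes

The generators emulate the study conditions: 60 Hz recording, a
0.30 × 0.30 m test-section cross-section, flow 0.10–0.25 m s⁻¹,
densities 100–1000 m⁻³, ~0.10 m of body outside the burrow, three
cameras on one flume side (two side by side, one above, ~0.85 m away,
1920×1080, ~1500 px focal length) built as exact pinhole DLTs.

The eel is an 8-point polyline along a circular arc bending downstream,
anchored at the burrow; lateral sway is a sinusoid whose amplitude grows
linearly from zero at the burrow to the nominal amplitude at the eye
(default 5 mm, 1 Hz), so the eye's sway has a closed-form VeDBA,
(2/π)A(2πf)², used as an oracle. Strikes arrive as a Poisson process
(default 0.3 s⁻¹); each is a straight lunge at 0.15 m s⁻¹ toward a
sampled prey position within 4 cm reach, ramped linearly out and back
with displacement scaled quadratically along the body; overlapping events
are skipped. Prey are non-swimming tracers seeded as a spatial Poisson
process and advected at (−U, 0, 0); an eel-length-to-flow-speed mapping
is left to the caller rather than hard-coded. Trial counts come from the
feeding-area forward model: captures ~ Poisson(ρU(πL²/2)T), control
losses ~ Binomial(released, loss fraction).

All generators are pure functions of (parameters, seed) using a single
`numpy` Generator per call.

What the synthetic data does **not** emulate: turbulence and
boundary-layer shear, prey escape or swimming, pose-estimation failure
modes (occlusion, identity swaps, confidence correlated with pose), lens
distortion, and camera desynchronization. Passing tests therefore
demonstrate that the pipeline's geometry, calculus, and bookkeeping are
correct and self-consistent — not that any particular field recording
meets the generators' assumptions.

## Problem sizes

The test suite and acceptance script use desk-scale sizes chosen as
comfortable for the statistics involved: 10 s scenes at 60 Hz (600
frames, 8 body points, 3 cameras), 1000 random point/rig round trips,
100–200 seeds for Monte-Carlo bands, and 500 seeds for the trial-count
parameter recovery (standard error ≈ 0.37 prey min⁻¹ on a mean of
≈ 23.6).

## Known limitations

* The drag model ignores skin friction, added mass, and unsteady forces
  during strikes; it describes quasi-static posture drag only.
* The Cd(Re) correlation is a generic smooth-cylinder fit; absolute drag
  values inherit its few-percent-level uncertainty, though scenario
  *ratios* are much less sensitive to it.
* The feeding-area model assumes every crossing prey is captured;
  it overestimates when parts of the semicircle are out of reach.
* VeDBA from triangulated positions double-differentiates measurement
  noise; with sub-pixel tracking at flume scale this is acceptable, but
  noisy tracks should be inspected before interpreting absolute values.
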