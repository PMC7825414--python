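# Methods

`backload` studies one question: how accurately can body-worn sensors —
inertial measurement units (IMUs) on up to five body locations plus pressure
insoles — estimate the net internal moment at the L5/S1 joint during manual
material handling, and which sensor locations matter?  Because raw
laboratory recordings of this kind are not publicly available, the package
pairs the estimation pipeline with a first-class synthetic-data generator
that produces dynamically consistent lifting trials with exact ground-truth
lumbar moments.  This note documents the models, the generator's
assumptions, the numerical choices, and what results on synthetic data do
and do not show.

## Body model and reference frames

The body is nine rigid segments: two feet, two shanks, two thighs, a
pelvis, and a trunk segment with the head and both arms lumped in.  A
handheld box is a point mass at the hand point.  Segment masses, lengths,
centers of mass and radii of gyration come from a standard anthropometric
proportion table (Winter-style fractions of body mass and height), stored
as data on each `Anthropometry` and overridable per participant.  The
lumped-arm simplification is deliberate: the estimation target is the
L5/S1 moment, which depends on the upper-body wrench as a whole, not on arm
articulation.  Its cost is that object-to-body distance is a free parameter
(the "grip distance") rather than an arm-posture consequence; the generator
treats grip distance as an explicit source of variation (below).

The global frame is X anterior, Y up, Z to the participant's right.  The
internal (muscle) moment resisting forward flexion — lumbar extension — is
the +Z component of the L5/S1 moment; lateral bending is the +X component.
Trunk orientation composes Z–X–Y (flexion, lateral lean, axial rotation);
forward flexion is a negative rotation about +Z under this frame.

## Trial synthesis

Each trial is a pick-and-place task: reach to the origin shelf, pick the
box, carry it upright, place it at the destination shelf, return to
standing.  Postures live in a 9-coordinate generalized space (absolute
sagittal angles of shank, thigh, pelvis; the trunk's three angles; a
global-frame arm offset of the hand from the chest).  A planar posture
solver produces each keyframe: a style table (squat: knee-dominant; stoop:
trunk-dominant; lateral and diagonal add lean and axial rotation) is scaled
by a depth parameter solved so the hand reaches the shelf height, and the
shank lean is solved so the body-plus-load center of mass sits over the
feet.  Keyframes are connected by rest-to-rest minimum-jerk interpolation;
velocities and accelerations are analytic derivatives of the interpolant.
The box's weight transfers on/off the body through a 0.1 s linear ramp
centered on the pick and place instants, both of which fall inside
stationary dwell phases, so no force discontinuity ever occurs.

Ground reaction forces are synthesized, not simulated forward: the per-foot
forces and centers of pressure are constructed from the whole-body inertial
and gravitational requirement, with the frontal-plane lever rule splitting
load between the feet and the CoP placement absorbing the sagittal and
frontal moment balance.  Every noise-free trial is therefore dynamically
consistent to machine precision, which is what makes the closure oracle
below meaningful.  The vertical-axis free moment under the feet is not
modeled; because it is purely vertical, it provably cannot contribute to
the extension (+Z) or lateral-bending (+X) components reported.

Keeping the CoP inside each foot's support polygon at all times constrains
the motion plan.  Three mechanisms achieve it: (i) every between-keyframe
transition carries a smooth "balance bump" on the shank coordinate — a
correction `c·(4s(1−s))²` of the minimum-jerk phase `s`, solved at the
transition midpoint, that vanishes with zero velocity and acceleration at
the keyframes — so mid-transition postures stay balanced; (ii) nominal move
duration is 2.0 s, slowed by 0.8 %/kg of box mass (heavy lifts are slower),
keeping inertial ZMP excursions inside the feet; (iii) the nominal stance
point sits mid-support (0.040 m anterior of the ankles).  With the default
battery, no sample is clipped; if an externally supplied motion does drive
the CoP outside the polygon, it is clipped with a logged warning and exact
consistency is lost for those samples.

### What the generator varies, and why

Real populations do not map trunk angle to lumbar moment one-to-one.  The
generator reproduces the main reasons:

* **Load-compensation posture.**  Carrying a load in front induces a
  compensatory trunk lean-back (0.006 rad/kg), and holding a load shifts
  the stance point forward by 1.3 mm/kg (postural under-compensation).
  Both are well-documented load responses.  The forward CoP shift matters
  methodologically: it is an *absolute* (body-size-independent) signature
  of load in the insole channels.  Raw force in newtons does not transfer
  across body masses — a heavy person bending unloaded produces the same
  vertical force as a light person bending with a box — and without the
  CoP signature a leave-one-subject-out model systematically hallucinates
  load for the heaviest held-out participant.
* **Movement habit.**  Each participant has a stable trunk-flexion share
  (trunk-dominant vs knee-dominant lifting; multiplicative gain, sd 0.08)
  and a personal grip distance (sd 0.02·height).  An earlier design also
  scaled the other segment angles per participant; it was removed because
  it injected systematic cross-participant bias into pelvis-derived
  channels without adding information, distorting the sensor-subset sweep.
* **Trial-to-trial variation.**  Keyframe angles are jittered (sd 2.5°,
  clipped at 2 sd), arm offsets by 1.5 % of height, grip distance by
  2.5 % of height per trial, and movement durations by 7 %.  Grip
  variation is deliberately invisible to any IMU but visible to the
  insoles through the CoP — the physical reason pressure insoles carry
  information no body-worn IMU can supply.

## Ground-truth moments and the closure oracle

`bottom_up_lumbar` runs a recursive Newton–Euler pass from each foot's
external wrench (GRF at its CoP) up through shank, thigh and pelvis, and
reports the net internal moment the lower body exerts on the trunk at
L5/S1 — the same route a lab takes from force plates.  `top_down_lumbar`
computes the trunk-plus-object gravitational and inertial wrench about
L5/S1.  For any dynamically consistent trial the two must agree; the test
suite asserts agreement within 1e-9 relative RMS on the full battery (the
observed discrepancy is ~1e-15, i.e. float64 round-off).  Static
closed-form cases (upper-body and object point masses at known anterior or
lateral offsets) pin the sign convention and magnitude.  Segment angular
dynamics use diagonal segment-frame inertia tensors from the
radius-of-gyration fractions, with the long-axis moment set to 0.3 of the
transverse value (slender-segment assumption).

Moments are reported in N·m and normalized to body weight × body height
(BW×BH) for modeling, the standard normalization for between-subject
comparison; the conversion is exactly invertible.

## Wearable channels

* **Idealized set (51 channels):** 8 segments × 3 Euler angles, 7 joints ×
  3 angles, and the idealized insole signals — the 3D GRF projected onto
  the sole normal (one value per foot) and the CoP in each foot's own
  frame (X toe-ward, origin at the heel).  Negative normal forces are
  floored at zero (an insole cannot pull), with a logged count.
* **Real-emulated set (179 channels):** a denser model-based export with a
  spine chain (L5, L3, T12, T8 interpolated between pelvis and trunk
  orientation at fractions 0.2/0.45/0.7/0.9, as motion-capture suits
  export), giving 11 segments × (3 Euler + 4 quaternion + 3 angular
  velocity + 3 linear acceleration) + 10 joints × 3 + insoles.  It is
  normally built from a noise-degraded trial.

Sensor-location ownership is conservative: a joint-angle channel exists
only when the sensors on both adjacent segments are worn; interpolated
spine segments belong to the nearest physical IMU (L5, L3 → pelvis; T12,
T8 → trunk).  With a zero noise configuration the shared channels equal
their idealized counterparts bit-for-bit.

Real-sensor degradation applies a per-trial multiplicative gain error and
additive white noise to the insole forces (defaults: gain sd 0.15, 20 N),
white noise to the CoP (10 mm), and constant-bias plus white rotation noise
to every IMU orientation (0.5° / 0.3°).  The magnitudes are the package's
own choices, set so that insole force variability — not IMU orientation
error — is the dominant degradation, consistent with how research-grade
pressure insoles compare against force plates (10–20 % force error) while
modern IMU orientation errors stay below a degree.  Angular-velocity and
acceleration channels are passed through clean; orientation-level noise is
the part that matters for this analysis.

## Estimation and evaluation

The regressor is a histogram-binned gradient-boosted tree ensemble
(scikit-learn's `HistGradientBoostingRegressor`; 100 trees, learning rate
0.1, 255 bins, 31 leaves, minimum 20 samples per leaf, squared-error loss).
Predictions are instantaneous: the channels at one time sample predict the
moment at that sample.  There is no hyperparameter search; the defaults are
fixed and exposed in `GbdtConfig`.

Cross-validation is leave-one-subject-out.  Per fold, the per-channel
z-score normalizer is fitted on the training participants only and applied
unchanged to the held-out one (constant channels are flagged and passed
through unscaled).  Accuracy is r² = 1 − SS_res/SS_tot per participant over
all their samples, averaged across participants (not squared Pearson —
switchable, but systematic over/under-prediction should count against a
monitoring tool); RMSE in BW×BH and converted to N·m with the cohort-mean
body weight and height; and MAPE restricted to samples whose true moment
exceeds 0.05 BW×BH, since percent errors diverge near zero.  Signal
importance is permutation importance on the held-out folds (shuffling
within each participant, 5 repeats), reported as the drop in r².  Note the
standard caveat: correlated channels shield each other under permutation,
so per-channel drops understate joint contributions and do not sum to the
baseline.  Paired subset comparisons use the two-sided Wilcoxon signed-rank
test over per-participant accuracies (exact null for n ≤ 25).

The sensor sweep enumerates all 62 reduced subsets of the six candidate
locations (trunk, pelvis, thigh, shank, foot, insoles — bilateral locations
worn as pairs) plus the full set, and runs the complete LOSO pipeline per
subset.  Ties in the best-per-size selection break toward fewer channels,
then lexicographic name.

## Problem sizes and numerical choices

The reference study is 10 participants × 100 tasks at 100 Hz (~790
samples/trial, ~790 k samples).  Because the estimator is per-sample,
training sets are decimated in time without information loss beyond sample
count: assembly keeps every 4th sample (25 Hz); the 63-subset sweep screens
at a further stride (every ~40th original sample) and the best-per-size
subsets are then re-evaluated at 4× more samples.  This two-stage protocol
mirrors screening-then-confirmation practice; at the screening size the
best-per-size curve carries ~5e-4 estimation noise, which matters only
where added sensors are nearly informationless (the static feet in this
no-stepping model).  The curve rises steeply to three locations and then
saturates; in the saturated tail, differences between cohort/jitter draws
can reach a few 1e-3 in either direction, so only the rise and the
saturation level are meaningful, not the ±0.003 ordering among the largest
subsets.  Random seeds: the cohort, battery, each trial, each
degradation and each importance run consume independent seeds derived from
a master seed; all pipelines are bit-reproducible given the master seed.

## What passing tests show — and what they do not

The synthetic cohort reproduces the *mechanisms* that make sensor fusion
work: posture dominates the moment, loads are invisible to IMUs alone,
insoles see both load magnitude (normal force) and load placement (CoP
shift), and per-sample force levels do not transfer across body masses.
On this data the pipeline shows the expected structure — trunk+insoles
around r² ≈ 0.93 versus trunk-only ≈ 0.82 with every participant improving;
insoles alone far behind; accuracy saturating beyond two locations; trunk
sagittal angle and insole normal force the two dominant signals; and the
insole benefit eroding under realistic insole noise and returning when the
insole channels are idealized.

Synthetic data are cleaner than reality in known ways: no soft-tissue
artifact, no stepping or gait, feet flat and stationary (so foot IMUs are
near-informationless here, more than in reality), no marker/model
registration error, arms massless beyond the lumped trunk, and movement
variability far more structured than human motor noise.  Absolute r²
values on this data therefore say nothing quantitative about hardware in
the field; the orderings and trends are the reproducible content.

## Known limitations

* Double support throughout; tasks requiring stepping are outside the
  battery.
* The support-polygon check uses an axis-aligned foot envelope.
* The 99-sensel pressure map is not simulated, only the exported totals
  (normal force, CoP).
* The spine-chain export interpolates orientations; its angular velocity
  and acceleration channels are blends of pelvis and trunk, not integrals
  of the interpolated orientations.
* MAPE is undefined (NaN) when no sample exceeds the threshold, as happens
  for the lateral-bending target on mostly sagittal batteries.
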