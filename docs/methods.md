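# Methods

This note records the models, conventions and numerical choices behind
the package, including the places where the underlying protocol leaves
the design open and a choice had to be made.

## Frames and conventions

The world frame is right-handed with Z up; X is the subject's front at
the start of each recording (heading is unobservable without a
magnetometer, so every recording carries its own front reference,
established over its first 0.5 s, during which the subject is assumed
quiet and facing the test direction).  Quaternions are scalar-first
Hamilton quaternions mapping sensor/segment-frame vectors into the world
frame.  Segment frames are anatomical: +Z up, +X forward, +Y left when
standing upright.  A level, static accelerometer reads +9.81 m/s² on its
z axis (the reaction to gravity).  Euler decompositions are intrinsic
Z-Y-X (yaw, pitch, roll), so a forward lean is positive pitch.  Units at
API boundaries: m/s², deg/s, seconds, metres; internal angle math is in
radians, reported features in degrees.

## Orientation estimation

The default estimator integrates the gyroscope and corrects the tilt by
a normalised-gradient step towards the accelerometer's gravity
direction, with gain `beta` (default 0.1 rad/s) and a 1 s high-gain
(0.5) warm-up seeded from the first accelerometer sample.  Two gates
suspend the gravity correction when the accelerometer is not measuring
gravity: a norm gate (skip when | |a|/g − 1 | > 0.05) and a rate gate
(skip above 20 deg/s, since fast body rotation implies linear
acceleration at any mounted sensor).  The gates bound the tilt error
injected during movement to well under 2° RMS on full task dynamics at
the cost of relying on the gyroscope alone during movement; between
calibrations, yaw drift is accepted.  Two caveats are inherent rather
than bugs: the normalised-gradient step has fixed magnitude `beta*dt`,
so the converged estimate dithers within a proportional band; and the
magnetometer path exists but is off by default (indoor fields are
rarely trustworthy).

The alternative complementary estimator takes pitch and roll from the
0.5 Hz low-passed accelerometer and yaw from the integrated world-frame
gyro z rate.  It is accurate only for quasi-stationary movement: signal
content at or above its cut-off is attenuated by the filter itself, so
it is not suitable for tracking the fast phases of the tests.

## Sensor-to-segment calibration

Stage 1 (quiet upright stance, ≥ 1 s): the mean measured gravity
direction is rotated onto the segment vertical; the quality score is
the RMS angular scatter of the per-sample gravity directions, rejected
above 5°.  Stage 2 (forward lean then partial squat): both movements are
sagittal, so the principal axis (largest eigenvector of Σ ωωᵀ) of the
stage-1-corrected angular velocity is the segment pitch axis.  It is
accepted only if it carries ≥ 0.8 of the rotational energy and the
cumulative rotation about it exceeds 10°; no minimum squat depth is
required beyond that.

Two ambiguities need resolving.  (1) The sign of the pitch axis: in a
lean-and-squat, trunk and shanks pitch forward but the thighs flex the
opposite way, so the sign cannot be fixed by "initial rotation is
forward" uniformly.  Each segment in the body model carries a
`flexion_sign` prior (+1 trunk/pelvis/shank, −1 thigh) and the axis sign
is chosen so the extremal cumulative rotation matches it.  (2) A purely
lateral lean is indistinguishable from a forward lean for a trunk
sensor taken alone (one dominant horizontal axis either way); it is
caught instead through the leg sensors, which a lateral lean does not
move (insufficient excursion → ambiguous-movement error).  This is a
known limitation: with a single trunk sensor the front direction is
taken on faith.

The sequence is recorded at the start and end of each session; the end
recording is preferred (sensors may settle during the first movements)
unless its dispersion or axis-energy scores fail, in which case the
start recording is used, and an error is raised if both fail.

## Posture, translation, COM, forces

The body is a tree of rigid segments rooted at the pelvis; each segment
has a length, a mass fraction, a COM offset along its long axis, an
attachment point on its parent (distal or proximal, plus a fixed offset
vector — the hips sit ±9 cm lateral of the pelvis origin) and a long
axis equal to ±Z of its anatomical frame (legs point down).  Forward
kinematics propagates joint positions from the root; segments without a
sensor inherit the parent's orientation.  The packaged six-segment model
uses standard anthropometric mass fractions summing to 0.94 (arms and
feet are not modelled; the weighted COM sum renormalises by the modelled
fraction).

Translation: a foot in ground contact is world-stationary.  Per frame
the anchor foot is the clearly lower one (height difference > 3 cm);
when neither foot clearly leaves the ground the shuffle fallback picks
the foot moving backward relative to the mid-foot point along the
torso's front direction, with a 2 cm/s dead band holding the previous
anchor.  The vertical offset keeps the anchor foot on the ground plane.
Turning in place violates the stationary-anchor assumption (both feet
pivot), so translation drifts up to roughly the stance-width arc during
a turn; phase durations and segment angles, which the features use, are
unaffected.

COM acceleration for the force balance is obtained by second-order
central differences after a zero-phase 5 Hz low-pass.  The total
vertical force m(g + a_com,z) is split between the feet in inverse
proportion to the horizontal distance from each foot to the COM ground
projection along the inter-foot line (the lever rule); a COM projection
outside the inter-foot span is clamped to the nearer foot and the frame
flagged; single support assigns everything to the stance foot.

## Segmentation and features

Rising from a chair is detected when trunk pitch exceeds 15° and trunk
pitch rate exceeds 20 deg/s, sustained for the 0.3 s debounce, and is
confirmed when the mean thigh inclination comes below 20° of vertical
within 6 s; sitting down mirrors it (thigh inclination rising through
45°, completing above 70°, with forward trunk lean over the descent and
no return below 20° mid-way, which rejects deep-crouch walking).  The
trunk signal is the C7-TH1 sensor's segment, which carries the full
lean.  Detected threshold crossings are then refined to the nearest
movement onset/offset — the last/first sample whose angular activity
falls below 2 deg/s, or the activity minimum in a bounded window — which
pins boundaries to the true phase edges independently of the threshold
values; the rise end uses the thigh-inclination minimum, and the sit
onset the end of the thigh's most-vertical plateau (3° band, robust to
fusion jitter during the preceding turn).  TUG turns are trunk yaw-rate
episodes above 30 deg/s sweeping more than 60°; the six phases are
sit-to-stand, walk out, first turn, walk back, second turn,
stand-to-sit.  All thresholds are configuration, not constants of the
method.

SWAP 82 enumerates, over the action windows {raising, between, sitting}:
peak signed anterior–posterior and peak absolute lateral inclination for
the two trunk sensors' segments over {raising, sitting}, plus min/max
inclination and mean/max angular speed for every modelled segment over
every window, on top of the four durations.  With six segments this
yields 4 + 8 + 36 + 36 = 84 features.  The protocol's advertised count
of 82 cannot be reproduced exactly from its published description (two
action windows give 60, three give 84); the enumeration here is
config-driven and its count asserted, and SWAP 4 is an exact subset.
There is no dedicated head sensor in the six-sensor setup; the C7-TH1
segment stands in for the head.

## Classifier and evaluation

A fully connected perceptron with two tanh hidden layers of equal width
(5, 7 or 10), a single sigmoid output for the faller probability, and
full-batch gradient descent on the cross-entropy loss for exactly 2, 4
or 20 epochs, optionally with an L2 penalty (coefficient 0.01).  The
underlying protocol does not state the optimizer; with the loss
normalised by the cohort size, a learning rate of 1.0 is needed for the
epoch budgets above to train at all, and reproduces the expected
qualitative ordering (2 < 4 < 20 epochs).  Features are z-scored inside
`fit` from the training data only, so leave-one-out evaluation cannot
leak the held-out subject into the scaling; each fold derives its seed
from the base seed plus the fold index, making the whole grid
deterministic.  Folds whose training split collapses to one class are
skipped with a warning and reported.

Metrics allow fractional confusion counts, because published summary
tables report mean rates whose implied counts for a fixed cohort are
non-integer.  For cross-checks against the published tables, sensitivity
is weighted by the 32-subject class and specificity by the 8-subject
class — the only assignment consistent with the published per-cell
accuracies.  One published aggregate cell is irreconcilable with its own
grid under any rounding (see `mobikit.benchmarks.KNOWN_INCONSISTENT`)
and is excluded from the ±1-percentage-point assertions.

## The synthetic test bed

The simulator is kinematic, not dynamic: joint-angle and position
profiles are raised-cosine ramps between postures, so velocities vanish
at phase boundaries and the derived inertial signals are continuous.
Legs follow prescribed hip and ankle paths through planar two-link
inverse kinematics, which keeps orientations, foot placement and
whole-body translation mutually consistent; profiles that reach full
knee extension are quartically flattened because the knee angle behaves
like the square root of the remaining hip drop there.  Walking uses
alternating steps with the hip lowered to keep the prescribed step
length reachable — a crouched gait, chosen for kinematic consistency
rather than realism.  IMU synthesis inverts the sensing model exactly
(gravity reaction plus linear acceleration of the segment mid-point in
the sensor frame; angular velocity in the sensor frame), with optional
white noise, constant gyro bias and random mounting misalignment.

Cohort defaults encode the intended contrast — fallers slower (raise
1.9 s vs 1.3 s, SD 0.2), more lateral sway (6° vs 3°), lower angular
speeds (scale 0.75 vs 1.0) — several of the induced features are
therefore ≈ 2–3 SD apart.  Cohorts are simulated at 50 Hz (single-trial
default 100 Hz), which keeps a 40-subject cohort under half a minute to
generate while leaving segmentation accuracy comfortably inside the
0.05 s budget at the rates used.

What passing the synthetic suite does **not** show: performance on real
bodies.  The simulator has no soft-tissue artefact, no sensor mounting
drift during a session, no physiological gait dynamics, and its classes
are cleanly Gaussian in the generating parameters.  Classification
accuracies near 100 % on synthetic cohorts validate the pipeline's
plumbing and protocol (no leakage, determinism, sane thresholds), not
clinical effect sizes.

## Known limitations

* Yaw is dead-reckoned between calibrations; long recordings with noisy
  gyros will drift in heading.
* Translation during pivot turns is biased (stationary-anchor violation).
* The front-direction calibration cannot detect a laterally performed
  movement from a single trunk sensor.
* The complementary estimator is only valid for quasi-static tasks.
* The published headline classification rates cannot be reproduced from
  data (the study's recordings are private); only their metric
  arithmetic is checked.
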