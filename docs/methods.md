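# Methods

This note documents the models, conventions, and design choices behind
`collaraccel`, and what the synthetic experiments do and do not
demonstrate.

## Signal model of the simulator

Each behaviour is parameterised by a `BehaviourSpec`:

- **static orientation** — the unit gravity direction in device axes
  (heave, surge, sway) characteristic of the posture. Standing and the
  upright gaits put gravity in +heave; stalking variants pitch the collar
  nose-down (gravity rotated towards +surge); lying puts most of gravity
  into sway (lateral surface on the ground); sitting tips the collar
  slightly back.
- **dynamic amplitude** (g) — the scale of the movement component,
  ordered lie < stand < walk < trot < canter < gallop so that
  neighbouring gaits genuinely overlap under sensor noise. The gallop
  amplitude (3.2 g) deliberately exceeds the low-capacity logger's
  ±2.3 g range, so that device saturates during galloping while the
  ±8.6 g device does not.
- **stride rate** (strides/s) and a **footfall pattern** — an ordered
  list of (limb, contact-onset phase, contact-duration fraction) over one
  stride cycle: walk is a 4-beat sequence (LH, LF, RH, RF at quarter-cycle
  offsets), trot a 2-beat diagonal pattern, canter a 3-beat (1–2–1)
  pattern, gallop a 4-beat hind–hind–fore–fore pattern with two
  suspension gaps. Each contact contributes a raised-cosine impulse in
  heave, a differentiated push-off component in surge, and a sway
  component whose sign alternates with limb side. A small multiplicative
  stride-to-stride jitter (3 % of amplitude) prevents bit-identical
  cycles.
- Non-gait movement (head movement, "other") is band-limited Gaussian
  wobble (≈1.5 Hz corner, per-axis RMS equal to the dynamic amplitude,
  weighted towards heave/surge as neck nodding would be).

Sensor noise is additive i.i.d. Gaussian per axis, default sd 0.05 g.
Stride rates (walk 1.0, trot 1.8, canter 2.2, gallop 2.8 strides/s) and
amplitudes are stated modelling assumptions chosen to be plausible for a
large cursorial felid, not measurements.

Ideal sessions are generated at 100 samples/s and then recorded through a
`DeviceProfile` by linear interpolation onto the device grid, symmetric
clipping at ±max range, and rounding to the nearest multiple of the
amplitude resolution. Interpolation (rather than decimation or polyphase
resampling) is the simplest convention that an independent oracle can
reproduce exactly; recording is idempotent per profile. Upsampling is
refused: every recorded trace derives from a strictly finer ground truth,
as with a dual-logger collar.

Sessions start with a "rail window" (default 10 s) in which the collar
hangs with gravity along +heave and no dynamics; a session-level
3-D rotation (`mounting_offset`) applied to the whole trace emulates a
non-centred collar mount.

## Calibration

The mounting correction is the minimal (axis–angle) rotation taking the
rail-window mean acceleration onto the expected gravity direction. Only
the component of the offset that moves gravity is observable from a
single static window — a residual twist about gravity itself is invisible
to an accelerometer — so recovery is asserted on the gravity direction
(error < 2° at noise sd 0.05 g), and the estimated rotation equals the
exact inverse of the planted offset only for tilt-only offsets. No
per-axis gain or bias is fitted: both logger models report in calibrated
g, so a rigid rotation is the whole correction. Windows whose mean
magnitude falls below 0.5 g are rejected as non-static.

## Feature conventions

- The rolling static window is **centred** with shrinking edges
  (`round(window·rate)` samples; sample *i* averages indices
  `[i − n//2, i + (n−1)//2]`). A centred window avoids phase lag between
  the static estimate and the raw signal; the choice is isolated behind
  one function and covered by a brute-force oracle test.
- Dynamic components are stored as absolute values, so per-axis sign
  information is deliberately discarded; VeDBA is computed from these
  absolute components (numerically identical to using signed residuals).
- pitch = arcsin(static surge / VeSBA), roll = arcsin(static sway /
  VeSBA), both in degrees, so an upright stance gives 0°/0° and a
  head-to-ground posture (gravity in surge) gives pitch 90°. Both are
  invariant to uniform scaling of the static vector.
- Anim.stat is defined here as the angle between the per-sample static
  vector and the calibrated resting orientation (default +heave) — a
  postural-deviation angle in [0°, 180°]. This is a declared convention:
  it is 0° at rest, 90° for orthogonal postures, and reduces to a
  function of pitch/roll only through the full static vector.

## Label handling

Labels are half-open intervals [start, end); a sample exactly on a
boundary belongs to the later behaviour. Samples covered by no interval
are "unassignable" and removed (with a reported count) before modelling —
the analogue of discarding footage in which the animal was obscured. The
ethogram hierarchy ships as a CSV (`fine,medium,coarse`); at the medium
level pounce folds into "other" (it is too instantaneous to categorise
reliably), while at the coarse level it counts as active. Collapsing
conserves total event counts by construction.

## Classifier protocol

Per-sample classification: each logging event is one case, with no
windowed summary features. The 60/20/20 split is uniform at random
(train ⌊0.6 n⌋, validation ⌊0.2 n⌋, test the remainder), seeded. Forests
grow two trees at a time (warm start) and stop when the two-block moving
average of validation accuracy improves by less than 0.1 percentage
points over the previous two-block average; the cap is 500 trees by
default (the stopping rule typically halts below 30 on these data).
Depth is refined over a small grid (default 5, 10, 20) by validation
accuracy, ties to the smallest depth. Test metrics are computed exactly
once per fit, enforced in code. Cross-validation is seeded 5-fold on the
training data, reporting mean ± sd per metric.

Metric conventions: accuracy is correct/total. MSE is the mean of
(1 − p(true class))² over cases — the per-event probability error
convention of the tree-ensemble framework whose reporting style these
outputs mirror — with RMSE = √MSE and r² = 1 − MSE/Var(numeric class
codes). For confident classifiers MSE ≈ error rate. Class imbalance is
left uncorrected, and "other" rows are kept in training and prediction;
they are disregarded only in the headline evaluation.

## Evaluation and device comparison

Per-behaviour "categorisation accuracy" is per-class recall (confusion
diagonal / row sum). Overall accuracy optionally disregards rows whose
*true* label is in a rag-bag set (default {"other"}): those rows leave
both numerator and denominator, while predictions *into* the rag-bag
from informative rows still count as errors. Misclassification shares
default to the row-total denominator (share of the behaviour's events),
with the errors-only denominator behind a flag, because both readings
occur in practice.

Device comparison per behaviour: a 2×2 table (device × correct/incorrect
validation events), Pearson χ² with df = 1 and no continuity correction;
if any expected cell is below 5 the test switches to Fisher's exact test
and reports the odds ratio in lieu of χ². Significance is two-sided at
0.05 with no multiple-testing correction; the verdict names the better
device or "n.d.". Comparisons run on the validation partition. The mean
difference is the unweighted mean of per-behaviour percentage-point
differences, excluding "other".

## Problem sizes

The default synthetic experiment ("full") is one simulated bout of ≈12
minutes (six passes of a 30-segment rest/stalk/chase template covering
all 17 behaviours) recorded at 30 and 50 samples/s — about 21,000 and
36,000 labelled events respectively — with forests capped at 200 trees
over the three-depth grid; the test suite uses a single-pass ≈2-minute
session with smaller forests. These sizes were chosen so a complete
six-model run finishes in minutes on one core while every behaviour
retains hundreds of events per split.

## What the synthetic experiments show — and what they cannot

The simulator reproduces the *structural* features the analysis relies
on: posture-separable static vectors, gait-periodic dynamics with
distinct footfall spectra, amplitude ordering across gaits, saturation of
the low-range logger during galloping, a calibratable mounting offset,
and a rag-bag class with heterogeneous signal. It does not reproduce
biomechanically calibrated cheetah dynamics, behaviour-transition
dynamics, inter-individual variation, or video-annotation noise, and its
classes are cleaner than field data. Synthetic model accuracies
(≈99 %) are therefore upper bounds that validate the pipeline's
correctness, not estimates of field performance; the published field
accuracies depend on the original recordings and are reproduced here
only where they are pure arithmetic over published tables (event-count
aggregates; accuracy differences and their means).

## Known limitations

- The rolling-window, angle, and Anim.stat formulas are declared
  conventions; alternative conventions (trailing windows, atan2-based
  angles) would change per-sample values but not the pipeline structure.
- A mounting twist about gravity is unobservable from the rail window
  alone and is left uncorrected; features driven by the static direction
  relative to rest are unaffected, but per-axis surge/sway assignments
  retain that ambiguity.
- The early-stopping rule evaluates on the same validation partition
  later used for depth selection and reporting, mirroring the modelled
  protocol; the untouched test partition guards against optimistic bias.
- Multiclass r² against numeric class codes depends on an arbitrary
  class ordering; it is reported for comparability of output format, not
  as a measure to optimise.
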