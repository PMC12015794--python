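# Methods

This note documents the models, procedures, defaults and design choices
behind `mannerkit`, and what the synthetic experiments do and do not show.

## Pipeline overview

Input is a directory of per-frame Body25 keypoint files (25 keypoints x
(x, y, confidence) per person per frame, origin top-left, y downward) plus
an interval annotation CSV (subject, segment, start/end seconds, label
set, unclear flag) and camera metadata (resolution, fps). Output is a
trained multi-label classifier and, in prediction mode, merged
"likely flapping"/"likely jumping" intervals.

Stages: person tracking → confidence filtering → normalization →
side-by-side feature layout → 15-frame windowing → class balancing →
subject-wise nested cross-validation → deployment training → interval
export.

## Person tracking

The pose estimator has no identity concept, so detections are matched
across frames by center of mass: the unweighted mean of all keypoints
with confidence > 0 (a detection with no such keypoint is treated as
absent). Matching is greedy in ascending distance between current centers
and each known person's last center, with ties broken by lower person id,
then file order. Design choices, made where the matching rule is
underdetermined:

- **max_jump = 200 px** (~10 % of a Full HD frame width): pairs farther
  apart are not matched and the detection founds a new person. No
  threshold is canonical; 200 px comfortably exceeds inter-frame motion
  at 25 fps while staying below typical person spacing. Configurable.
- A person missing from a frame keeps its id and last known center (no
  motion model); someone re-entering near where they left resumes their
  id, someone entering far away gets a fresh id.
- Greedy vs optimal: on simulated multi-person scenes the greedy pairing
  equals exhaustive minimum-cost assignment in ≥ 99 % of frames (tested);
  greedy is kept for determinism and simplicity.

## Features

- Keypoints with confidence **strictly below 0.6** are replaced by the
  missing encoding (0, 0, 0); a keypoint at exactly 0.6 is kept. Missing
  data stays zero — no interpolation, keeping preprocessing minimal and
  the feature a pure function of the frame.
- Coordinates are divided by frame width/height into [0, 1], making the
  features resolution-independent (verified by rendering the same scene
  at 1x and 2x). Out-of-frame coordinates are clamped with a warning.
- Per frame, the six arm keypoints (right/left shoulder, elbow, wrist) of
  up to five persons are concatenated in ascending person-id order:
  5 persons x 6 keypoints x (x, y) = 60 features. Absent persons/slots
  are zeros; with more than five tracked persons the lowest ids win.
- Annotated intervals are tiled into consecutive **non-overlapping**
  15-frame windows from the interval's first frame; a remainder under 15
  frames is dropped, so intervals shorter than 0.6 s at 25 fps produce
  nothing. Non-overlap avoids train/test leakage between windows of one
  interval and matches the reported window-count magnitudes. Each camera
  is windowized independently (two-camera recordings double as data
  augmentation).

## Labels and balancing

The coding scheme has seven categories (flapping, clapping, jumping,
hand/finger, legs, tiptoeing, body). Only flapping and jumping are
classifier targets — the others were too rare or unreliably coded — so a
window's label is the pair `[flapping ∈ labels, jumping ∈ labels]`.
Positives are windows whose interval contains flapping or jumping
regardless of co-occurring categories; the negative pool holds windows
from intervals with an empty label set; windows from unclear-flagged
intervals or from intervals carrying only non-target mannerisms join
neither side. Balancing draws exactly |positives| negatives uniformly
without replacement across all subjects (seeded).

## Classifier

Three stacked LSTM layers (the first two return sequences, the third its
final hidden state), one dropout layer, and a dense 2-unit sigmoid head;
binary cross-entropy averaged over both outputs; Adam. The two outputs
are computed independently, which is what makes the head multi-label.
Prediction thresholds each probability at 0.5 with a ≥ convention.

The cell follows the standard equations (update/forget/output gates via
sigmoid, candidate via tanh, `a = Γo * tanh(c)`). A `strict_paper` mode
computes `a = Γo * c` — the hidden update as it is sometimes printed with
the tanh omitted. The production network uses the standard form, since
that is what mainstream training toolkits actually compute; the strict
variant is kept so the as-printed arithmetic remains testable. The two
agree to 1e-6 whenever |c| < 1e-3.

### Training engine

Forward, backpropagation through time, and Adam are implemented directly
on numpy arrays. Correctness is established two ways: the vectorized
fused-gate cell is compared element-wise against an independent per-gate
reference implementation (100 random draws, agreement ~1e-16), and the
analytic gradients are compared against central-difference numerical
gradients on a small network.

Numerical choices:

- **Input standardization.** Raw features live in [0, 1] with a large
  constant component (static body position) and a small discriminative
  variance (the oscillation). Trained as-is at desk budgets, the
  optimizer fits base rates by inflating weight magnitudes, saturates the
  recurrent state, and the signal gradient vanishes. The engine therefore
  standardizes each input feature using training-set mean/sd (constant
  features are centered to exactly 0 and left at scale 1). The statistics
  are stored with the model and applied at inference; the feature-level
  contract (15x60 in [0, 1]) is unchanged.
- Initialization: Glorot-uniform weights, zero biases except the forget
  gate at 1; seeded, so training is deterministic for a fixed
  (data, config).
- Dropout is inverted dropout after the third LSTM layer only; identity
  at inference.
- Loss clipping at 1e-12 for numerical stability; a non-finite loss
  aborts with diagnostics.

### Configurations

Tuned space: units per layer ∈ {128, 256, 384, 512}, dropout
∈ {0, 0.05, 0.10, 0.15}, batch size ∈ {16, 32}, Adam learning rate
3e-4, 1000 epochs (`paper_config` preset, hours of compute). The `desk`
preset — used by the examples, tests and the acceptance benchmark — runs
32/32/32 units, batch 16, 30 epochs, and learning rate 3e-3: the rate is
scaled up one order as compensation for training 30 epochs instead of
1000. Problem sizes throughout the test suite (4-20 subjects, 12-24 s
segments) were chosen so a full nested cross-validation completes in
about a minute on one CPU.

## Evaluation

Per label, confusion counts give accuracy (TP+TN)/(P+N), recall
TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP), and
F1 = 2TP/(2TP+FP+FN); any 0/0 denominator yields 0 with a warning. The
macro average is the unweighted mean over the two labels. Reported values
are rounded to 3 decimals with exact half-ties resolved downward — the
convention under which the published macro column reproduces from its
printed per-label values (their unrounded fold means sat just below the
midpoints).

**Splitting.** The outer 3-fold split uses scikit-learn's
`StratifiedGroupKFold` with subjects as groups and the label powerset
(none/flapping/jumping/both) as strata — the minimal multi-label
extension of single-label stratification. Subject disjointness between
train and test is additionally hard-asserted. A `random` mode
(`StratifiedKFold`, subjects ignored) exists for quantifying the
optimistic bias of identity leakage.

**Inner loop.** Hyperparameters are tuned by budgeted successive halving
over the discrete space: `budget` configurations are sampled uniformly,
each trains for epochs/9 on an inner split of the outer-training data and
is scored by validation macro F1; the top third survives with a tripled
epoch allowance until one remains. Ties keep the earlier-sampled
configuration. The inner split is grouped by subject when at least four
subjects are available, else stratified over windows. Successive halving
replaces the more elaborate bracketed scheduler sometimes used for this
search: the scientific content is the space and the nesting, not the
scheduler.

**Deployment.** The per-fold winners are averaged — integer fields
rounded half-to-even, dropout to 3 decimals — and one final model is
trained on the full dataset with that configuration.

## The simulator

The simulator emits what the pose estimator would for a free-play
observation: per-frame Body25 JSON for a child plus up to two static
adults (tester, caregiver), optionally a walker who enters and leaves
view, from two cameras at 1920x1080 / 25 fps, the second camera an
x-mirrored view of the first.

- Skeleton: a fixed upright stick-figure template of the 25 keypoints,
  scaled per person (child 0.213 of frame height, adults ~0.36) with
  i.i.d. Gaussian jitter, σ = 2 px, per keypoint per frame.
- Flapping: vertical sinusoid `amp·sin(2π f t)` on wrists and elbows,
  default 4 Hz / 40 px — a fast arm oscillation an order of magnitude
  above the jitter. Jumping: the same form applied to all 25 keypoints,
  default 2 Hz / 60 px. Combined behavior sums both. Adults never carry
  behavior offsets.
- Confidence: Beta(8, 2) rescaled into [0.6, 1], mixed with probability
  `dropout_prob` (default 0.05) of Uniform(0, 0.6) — so the 0.6 filter
  removes exactly the dropout mass.
- The default cohort gives each subject two 4 s mannerism intervals
  (cycling flapping / jumping / both across subjects) inside a 24 s
  segment, leaving 16 s of no-mannerism time so the negative pool always
  exceeds the positives; every fifth subject has a walker crossing
  mid-segment.

Everything is deterministic given the config (including its seed); camera
2 is derived from camera 1, so both are bit-identical across runs.

**What the simulator does not emulate** — and hence what synthetic
results cannot show: real pose-estimator noise is structured (occlusion,
left/right swaps, person merges), children move around the room, real
flapping is neither sinusoidal nor stationary, and behaviors beyond
flapping/jumping (clapping, fidgeting) that confuse real classifiers are
absent. The near-perfect synthetic benchmark (macro accuracy ≈ 1.0 on
unseen subjects, 20-subject clean cohort) demonstrates that the pipeline
wiring — tracking, featurization, windowing, subject-wise splitting,
training — recovers scripted kinematics; it says nothing about accuracy
on real video, where the corresponding published figures are far lower.

## Known limitations

- Only arm keypoints are used; jumping detection would likely benefit
  from leg keypoints.
- Windows tile per annotated interval; a deployment system tiling whole
  segments will see boundary windows mixing behaviors.
- The tracker has no appearance model; two people crossing within
  `max_jump` px can swap ids.
- `strict_paper` mode exists for arithmetic fidelity only; it is not a
  trainable configuration of the engine.
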