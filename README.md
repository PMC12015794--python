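# mannerkit

Multi-label classification of motor mannerisms — arm **flapping** and
**jumping** — from skeletal-tracking keypoint streams, with subject-wise
nested cross-validation and a kinematic simulator.

## The problem

Restricted and repetitive behaviors (RRBs) such as arm flapping are early,
diagnostically relevant markers of autism spectrum disorder, but manual
coding of videotaped behavioral observations is slow and inter-rater
agreement for mannerism items is poor. A post hoc pipeline can help: a
pose estimator (Body25 convention: 25 keypoints per person, one JSON file
per video frame) turns existing videos of free-play sessions into
de-identified coordinate streams, and a sequence model classifies short
windows of those streams. `mannerkit` implements that pipeline for
researchers and clinical coders:

- **openpose_io** — read/write Body25 per-frame JSON; assign stable person
  ids across frames by nearest-center-of-mass matching.
- **features** — discard keypoints with confidence < 0.6, normalize
  coordinates by the frame resolution, lay the six arm keypoints
  (shoulder/elbow/wrist, both sides) of up to 5 persons side by side
  (5 × 2 × 6 = 60 features), and tile annotated intervals into
  non-overlapping 15-frame windows.
- **annotations** — the seven-category mannerism coding scheme, its
  projection onto the `[flapping, jumping]` label pair, and 1:1
  undersampling of no-mannerism windows.
- **model** — a stacked 3-layer LSTM with dropout and a 2-unit sigmoid
  head, trained with binary cross-entropy (Adam); implemented in numpy with
  a per-gate reference cell for verification.
- **evaluation** — per-label confusion metrics, macro averaging,
  subject-wise stratified-group nested 3-fold cross-validation with a
  successive-halving hyperparameter search, and the mean-hyperparameter
  deployment rule.
- **sim** — a kinematic simulator (child + adults, two mirrored cameras,
  scripted flapping/jumping sinusoids, confidence dropout) so the whole
  pipeline is testable without video data.

## The model

Each sample is a window $X \in [0,1]^{15\times 60}$. A recurrent cell
keeps hidden state $a^{\langle t\rangle}$ and cell state
$c^{\langle t\rangle}$ (both zero at $t=0$), updated per timestep with
$z = [a^{\langle t-1\rangle}, x^{\langle t\rangle}]$:

$$\Gamma_u = \sigma(W_u z + b_u),\quad
  \Gamma_f = \sigma(W_f z + b_f),\quad
  \Gamma_o = \sigma(W_o z + b_o)$$

$$\tilde c^{\langle t\rangle} = \tanh(W_c z + b_c),\qquad
  c^{\langle t\rangle} = \Gamma_u * \tilde c^{\langle t\rangle}
    + \Gamma_f * c^{\langle t-1\rangle},\qquad
  a^{\langle t\rangle} = \Gamma_o * \tanh(c^{\langle t\rangle})$$

Three such layers are stacked (the first two emit full sequences, the
third its final hidden state), followed by dropout and a dense layer with
two sigmoid units. Each output is thresholded at 0.5 independently, so a
window is labeled "no mannerism" `[0,0]`, "flapping" `[1,0]`, "jumping"
`[0,1]`, or both `[1,1]` (multi-label). A `strict_paper` cell variant with
$a^{\langle t\rangle} = \Gamma_o * c^{\langle t\rangle}$ (no tanh on the
cell state) is kept for fidelity testing.

Evaluation is **subject-wise**: the outer 3-fold split groups windows by
child and stratifies on the label powerset, so models are always scored
on children they never saw — the setting that matters for diagnostics.
Per label, accuracy, recall, specificity, precision and F1 are computed
from confusion counts; the macro average is the unweighted mean over the
two labels.

## Worked example

```bash
python examples/train_and_evaluate.py
```

simulates an 8-subject cohort, balances classes, and runs subject-wise
nested 3-fold cross-validation at desk scale, printing:

```
balanced dataset: 384 windows from 8 subjects
fold 0: test subjects ['s01', 's05', 's07'], macro accuracy 1.000, macro F1 1.000
fold 1: test subjects ['s06', 's08'], macro accuracy 0.995, macro F1 0.993
fold 2: test subjects ['s02', 's03', 's04'], macro accuracy 0.993, macro F1 0.990
macro accuracy mean (min-max): 0.996 (0.993-1.000)
deployment hyperparameters: HyperparameterSet(units_layer_1=32,
    units_layer_2=32, units_layer_3=32, dropout_rate=0.067, batch_size=27)
```

Each fold line reports how well the fold's model recognized mannerisms in
windows from subjects excluded from its training; the deployment model
averages the per-fold tuning winners and retrains on everything. The other
examples cover simulation (`simulate_scene.py`), tracking
(`track_persons.py`), featurization (`featurize_windows.py`), the LSTM
cell equations (`lstm_cells.py`), and interval annotation
(`predict_intervals.py`, which prints `likely flapping` /
`likely jumping` spans recovered on an unseen subject).

A thin CLI wraps the same stages for shell use:

```bash
mannerkit simulate  --config pipeline.yaml
mannerkit featurize --config pipeline.yaml
mannerkit evaluate  --config pipeline.yaml --split subject_wise --seed 1
mannerkit train     --config pipeline.yaml
mannerkit predict   --config pipeline.yaml
```

## Scope

The pose-estimation network itself is out of scope: `mannerkit` consumes
its output format. The study's videos are private; the simulator is a
deliberately simple stand-in whose limits are discussed in
`docs/methods.md`.
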