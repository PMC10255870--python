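# Methods

## Problem and supervision model

The task is to predict how many repetitions of an activity a
variable-length stretch of multichannel accelerometer data contains.
Supervision is weak: during training each sequence carries a single
integer — its repetition count — and nothing about where or how long the
repetitions are.  Counts are defined through *activity ends*: given a
dense per-sample class track (0 = null), the final sample of every
maximal run of a non-null class is one completed repetition, and a
sequence's weak label is the number of such end markers inside its
half-open interval `[start, end)`.  An activity cut by a segment
boundary is therefore credited to whichever sequence contains its final
sample — completions are counted, not overlaps.  A direct class change
between two non-null classes ends the first run: back-to-back distinct
activities each count.  `merge_classes` lets activity pairs that always
occur consecutively (open then close the same object) be collapsed into
one class so the pair counts once.

## Preprocessing and segmentation

Each channel is min–max scaled to [0, 1] with statistics from the whole
recording, before segmentation.  Scaling is per channel because channels
have heterogeneous offsets and ranges; the quotient
`(x − min)/(max − min)` is applied directly so channel extremes land on
exactly 0 and 1, and a zero-range (dead) channel maps to all-zeros
rather than aborting.  Normalizing before splitting leaks the
recording's extremes into every split; this mirrors the intended
workflow (normalize once, then divide) and is accepted knowingly.

Cut points are `n` strictly increasing integers in `(0, T]` with every
inter-point gap (including from 0) at least `min_len` samples, default
one second of samples — shorter sequences carry almost no usable signal.
They are sampled uniformly over the feasible set by drawing the slack
above the mandatory minimum gaps directly (sorted uniform offsets).
This is equivalent in distribution to rejection-resampling independent
uniform cuts until the gap constraints hold, but has no failure mode:
for realistic settings (e.g. 95 segments of ≥ 98 samples in a 53k-sample
recording) the acceptance probability of plain rejection is
astronomically small.  Samples after the last cut are discarded.
Consequently, for every draw the weak counts conserve exactly:
`Σ weak_count = #ends in [0, last cut)`.

A corpus is built by segmenting the same recording `replication` times
with independent cut draws — replicates contribute fresh sequence
lengths and counts rather than verbatim copies — pooling, shuffling
(seeded), and assigning exactly `n_test` sequences to test,
`val_fraction` of the remainder to validation, and the rest to training.

## Synthetic data generator

The generator emulates the structure of a multi-sensor arm-worn study of
repetitive manipulative gestures: C channels (default 60 ≙ 20 triaxial
sensors) at 98 Hz in milli-g.  A recording alternates null gaps with
`n_instances` activity motifs.  A motif is a Hann-windowed sinusoid —
it ramps from exactly zero and back — with duration drawn from
`motif_duration_s` (default 0.5–1.5 s), frequency from `motif_freq_hz`
(2–5 Hz, the band of deliberate hand/arm gestures), amplitude 1000
milli-g (≈ 1 g, gesture scale), on a subset of channels
(`active_channel_fraction`, default 0.5).  Gaps are 1–3 s: discrete
maintenance-style gestures are separated by pauses of seconds.
Gaussian sensor noise (sd 30 milli-g) is added everywhere.

A gesture class is *stereotyped*: the engaged-channel subset and the
relative phase pattern across those channels are drawn once per
recording, while duration, frequency and a global phase offset vary per
repetition.  Fully independent per-channel phases per repetition would
make single repetitions arbitrarily invisible to any fixed linear
projection (the projected amplitude `|Σ_c w_c e^{iφ_c}|` would be
redrawn each time), which models nothing physical about repeated
gestures.

What the generator does *not* emulate: real gesture morphology
(asymmetric, non-sinusoidal accelerations with gravity reorientation),
inter-subject variability, drift, or overlapping activities.  Passing
tests on this generator show that the pipeline's bookkeeping is exact
and that the training procedure can recover counts from clean repeated
structure; they do not certify accuracy on real recordings.

## Model

Per time step, two time-distributed dense layers (C → C linear → 2
ReLU) compress each sample; a single-unit LSTM with logistic gates and
*linear* cell activation integrates the feature stream into one scalar
per step (the step signal); a masking layer thresholds the signal at τ;
a counting layer returns the number of maximal non-zero regions of the
mask (rising edges, a leading 1 counting as an edge).  At C = 60 the
model has 3,798 parameters.  Hidden sizes above 1 are supported through
a linear read-out to one scalar.

Two numerical guards are required by the linear cell activation.  The
candidate–hidden feedback loop is an unbounded linear system, so the
cell state is clipped to ±`cell_clip`; without it forward passes
overflow.  The clip default is deliberately small (1.2): it also keeps
plateaus of the signal within gradient reach of the threshold — with a
large clip, a signal riding far above τ saturates the relaxation and
receives no gradient at all.  Optimizer steps are additionally
global-norm clipped.

## Training procedure

The mask and count layers have no useful gradients, so training works
through the logistic relaxation `s_t = σ(k(h_t − τ))` of the mask.  The
relaxed region count is the rising-edge sum
`s_1 + Σ_t max(0, s_t − s_{t−1})`, which converges to the hard count as
`k → ∞` for signals that never equal τ exactly.

Direct minimization of the relaxed count loss fails from generic
initializations, for reasons verified experimentally in this codebase:

* at large `k` the relaxation saturates and all gradients vanish
  (training freezes at "predict 0");
* at small `k` the objective admits degenerate optima in which many
  sub-threshold ripples sum to the label without the signal ever
  crossing τ — the hard path still counts 0 while the soft loss is
  near-zero;
* a signal whose first τ-crossings are rippled produces hundreds of
  spurious regions, a huge loss, and an immediate retreat below
  threshold;
* the rising-edge functional gives exactly zero first-order gradient
  for splitting a saturated merged plateau.

Fitting therefore proceeds in three stages:

1. **Mass warm-up** (default 40 epochs, Adam 1e-3, k = 5): minimize
   `Huber(Σ_t s_t / D − y)` with `D` = `expected_event_samples` (default
   98, one second — the center of the motif-duration range and a
   generic prior for gesture-scale events).  This density objective has
   gradients everywhere, no region pathology, and positions activity
   mass over the events.
2. **Threshold calibration**: τ is chosen by grid search (0.05–1.15 in
   steps of 0.025) minimizing the hard-path mean absolute count error on
   the *training* split.  The counting head needs a threshold but
   nothing fixes its numeric value, and the warm-up determines the
   signal's scale only up to an offset; calibrating one degree of
   freedom on 300 sequences is ordinary decision-threshold selection.
3. **Count fine-tuning** (Adam 1e-4, k annealed 5 → 20 by doubling):
   minimize `Huber(soft count − y) + λ·mean(s(1−s))` with λ = 0.3.  The
   binarization penalty makes intermediate mask values costly, closing
   the sub-threshold degeneracy.  τ is re-calibrated every five epochs.
   The learning rate halves after every 15 consecutive epochs without
   validation improvement (at most 4 times), and fine-tuning stops after
   `patience` stalled epochs.

Mini-batches of 2 variable-length sequences are padded and masked; the
recurrent kernels never read past a sequence's true length, so padded
batch processing is exactly equivalent to per-sequence processing (this
is asserted in the tests, exactly on counts).  Early stopping and
best-epoch restoration monitor the *hard-path* mean absolute error on
the validation split: soft losses at different annealed `k` are not
mutually comparable, and the hard count is the deployment metric.  Gate
biases are initialized as a leaky integrator (input −1, forget +2.5,
output +1) so the initial signal is a smooth envelope rather than white
ripple.  The Huber transition point is 1.0 — quadratic within one
repetition of error, linear beyond, robust to the occasional
extreme-count sequence that random segmentation produces.

Inference always runs the hard path with the calibrated τ, so
predictions are integral and non-negative by construction; no rounding
is ever needed.

## Evaluation

Over a test corpus the package reports: exact-count accuracy (fraction
of sequences predicted exactly), mean absolute error, a mean percentage
accuracy, and the signed-error histogram (also collapsed to |error|
bins).  The per-sequence percentage accuracy is defined here as
`100 · max(0, 1 − |ŷ − y| / max(y, 1))`: relative accuracy with a guard
making zero-count sequences well defined (any miss on a zero-count
sequence scores 0).  This is a reconstruction — the quantity is
conventionally reported but rarely defined algebraically — and its
absolute values should not be compared across papers.  Every report
cross-checks itself: accuracy must equal the histogram mass at zero and
the MAE must be recomputable from the histogram.

## Scaled-down study and known limitations

The bundled end-to-end study (also run by `scripts/acceptance.py`) uses
6 channels as a scaled stand-in for the 60-channel network: 170 motifs
of 0.5–1.5 s, four replicate segmentations into 95 sequences each,
pooled into 300 train / 30 validation / 50 test sequences with counts
spanning roughly 0–6.  One training run takes a few minutes on one CPU.

Two limitations are documented deliberately:

* **Ceiling from boundary cuts.**  Random cut points land inside motifs.
  A motif cut near its end is *seen* by the sequence but its end marker
  — hence its label credit — belongs to the next sequence.  A detector
  that counts every visible activity bump therefore overcounts such
  sequences by one; an exact-count ceiling of roughly 0.6–0.8 applies to
  any purely envelope-based detector on this corpus (measured with an
  oracle detector).  Exceeding it requires end-sensitive counting, which
  the single-unit recurrence can only partially acquire from weak
  labels.
* **Seed-dependent optimization.**  The relaxed count objective has
  data-dependent attractors; different parameter initializations
  converge to behaviorally identical solutions, so restarts do not help,
  and some data draws land in attractors with merged or missed regions.
  Across seeds, held-out exact accuracy typically falls between 0.3 and
  0.7 with the large majority of errors within ±1 repetition.  The
  training procedure here is a reconstruction — how the original
  architecture's authors passed gradients through the mask and count
  layers is not described in their report — and this brittleness is an
  honest property of that reconstruction.
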