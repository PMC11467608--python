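# Methods

`ocochew` implements a window-classification pipeline for detecting chewing
and eating segments from optomyography (OCO) sensors embedded in a glasses
frame. This note documents the model and the package's own design choices,
including everything the problem statement leaves open.

## Signals and data model

Four optical sensors track skin displacement (mm) in the X-Y plane over the
left/right cheek (zygomaticus region) and left/right temple (temporalis
region), giving 8 channels in the canonical order
`O_RC_x, O_RC_y, O_LC_x, O_LC_y, O_RT_x, O_RT_y, O_LT_x, O_LT_y`.
Recordings are uniformly sampled; the default rate is **50 Hz**, chosen so
that the 15-sample rolling median used by the statistics chain spans 0.3 s.
The sampling rate and sensor noise floor are configuration, not fixed
truths. Displacements are bounded by a configurable plausibility limit
(30 mm, the sensors' stated operating range). Runs of missing samples up to
0.2 s are linearly interpolated; longer gaps are an error, because the
median filters assume uniform sampling. Time is seconds from recording
start; annotation intervals are half-open `[start, end)`.

## Synthetic cohort generator

No public recording of this sensor type exists, so the generator produces
cohorts with the statistical structure the method relies on:

* **Eating** is bite-structured: bursts of raised-cosine chew cycles (one
  positive lobe of the magnitude signal per masticatory cycle) at a
  per-bite rate drawn uniformly from **0.8–2.3 chews/s**, separated by
  pauses. Bite length ~ Uniform(5, 20) chews; pause ~ Uniform(0.5, 3) s.
  Each cycle emits one ground-truth event time, so peak-counting has an
  exact truth. Per-chew amplitude jitter is ±20%.
* **Speaking** and **clenching** are non-periodic band-limited magnitude
  envelopes (Butterworth low-pass at 4 Hz and 0.3 Hz respectively) — the
  former irregular and faster, the latter near-static.
* **Idle** blocks contain sensor noise only.

Magnitude envelopes are split into X/Y by a random constant direction per
sensor and block, and additive Gaussian sensor noise (default σ = 0.001 mm
per axis) is applied everywhere.

Amplitudes are calibrated so the **mean combined left+right magnitude**
during each activity hits the target of the study conditions the package
replicates: cheek 0.113 / 0.036 / 0.008 mm and temple 0.027 / 0.008 /
0.002 mm for eating / speaking / clenching. Per-participant log-normal
multipliers (σ = 0.35, shared across activities so each participant's
activity ordering matches the population ordering) model between-person
variation; a smaller per-activity jitter (σ = 0.10) prevents exact
proportionality. Within-participant spreads are free parameters defaulted
plausibly — no published variance figures exist for them.

The generator does **not** model skin mechanics, sensor optics, drift, or
motion artifacts; passing tests demonstrate the pipeline's correctness and
its behavior under the assumed signal structure, not performance on real
hardware data.

Determinism: each participant gets an independent RNG substream seeded by
`(cohort_seed, participant_index)`, so regenerating any participant is
reproducible in isolation.

## Preprocessing

*Statistics chain*: per-sensor Euclidean magnitude → left+right sum per
region (cheek, temple) → centered rolling median, 15 samples. *Detection
chain*: kernel-5 median filter per channel (the "fifth-order" filter is
interpreted as kernel size 5) → partially overlapping windows (default 4 s
window, 1 s slide; trailing partial window dropped) → per-channel one-sided
FFT magnitude (DC removed, `window_len // 2` bins). All filters use
reflect padding to avoid amplitude bias at meal boundaries. A window is
labeled *chewing* iff at least 50% of its samples lie inside
eating-annotated intervals, symmetric with the segment-detection criterion.

## Window classifiers

Four architectures, all implemented on a compact numpy layer library
(`ocochew.nn`) with explicit backward passes, verified by numerical
gradient checks:

| arch | structure |
|---|---|
| `cnn2d` | 3 × [conv (5×3, same) → group norm (8 groups) → ReLU → max pool] over the (time × channel) plane, then 2 × 128-unit dense layers |
| `convlstm` | the same conv stack → sequence over the pooled time axis → 2 LSTM layers (128 hidden) → final hidden state |
| `attention` | 4 conv blocks with 64 feature maps → 2 LSTM layers → additive (Bahdanau-style) attention pooling |
| `cnn1d` | one 256-filter conv along time → max pool → flatten, fused with per-channel mean/variance/absolute-sum statistics → 1024-unit dense layer |

Open architecture details are package choices recorded in `ModelConfig`:
conv channel widths default to (16, 32, 64) with time pooling (4, 2, 2) —
sized so a leave-one-group-out sweep runs on a single CPU; kernel 5 along
time and 3 across channels; channel-axis pooling 2 while at least 2
channels remain. The FFT features enter `cnn2d`/`convlstm`/`attention` as
extra channels after linear interpolation to window length; `cnn1d` uses
time-domain plus statistical features only. Time, frequency, and
statistical inputs are all z-scored per channel with training-fold
statistics. Computation runs in float32 (float64 available via
`ModelConfig.dtype` and used by the gradient-check tests).

Training: Adam (lr 1e-3), cross-entropy, batch size 256, up to 100 epochs,
early stopping on validation F1-macro with patience 15, best-validation
weights restored. Weights use orthogonal initialization; biases start at
zero (a bias vector has no orthogonal form). When validation F1 ties the
running best, the *latest* tied weights are kept while patience still
counts from the last strict improvement — with a single easily-classified
validation participant, F1 can saturate at epoch 1, and keeping the most
trained tied weights avoids freezing an underfit model. Reduced-scale runs
(tests, demo pipeline) override epochs/patience/batch size explicitly; in
particular the batch size must not exceed the training-set size by much,
or each epoch degenerates to a single optimizer step. No class reweighting
is applied; residual imbalance effects are handled downstream by HMM
smoothing.

## Eating-segment detection and chew quantification

Window predictions are smoothed by a 2-state (noneating/eating) HMM over
the binary hard labels, decoded with Viterbi. Parameters are fixed from
training-fold statistics: state persistence `1 − 1/mean-run-length` of the
true labels (floored at 0.90), emissions equal to the classifier's
training-fold confusion rates (clamped to (0.01, 0.99)), initial
distribution equal to the label base rate. Maximal runs of the eating
state become segments spanning first-window start to last-window start
plus the window length.

Within a segment, the per-sensor magnitude with the highest RMS is
selected (ties resolve in canonical sensor order), median-filtered
(kernel 5) and band-passed to 0.5–3 Hz with a zero-phase second-order
Butterworth (applied forward-backward so peak timing is undistorted).
Chews are peaks passing three gates, all config-exposed defaults chosen
a priori: height ≥ 0.3 × filtered RMS, minimum spacing `fs / 3` samples
(the 3 chews/s band ceiling), prominence ≥ 0.5 × median retained-peak
height. The chewing rate is the arg-max of the FFT magnitude of the same
filtered signal restricted to 0.5–3 Hz, zero-padded to a bin spacing of
at most 0.02 Hz. Chew counts and rates are reported **per segment**.

## Statistics

Per participant and region, the mean of the smoothed combined magnitude
over all samples of each activity forms one observation. The three
activity pairs in each region are compared with two-sided Wilcoxon
signed-rank tests: zero differences dropped, midranks for ties, the exact
convolution null distribution of W⁺ for n ≤ 25 and a normal approximation
with tie and continuity corrections above, reported statistic
W = min(W⁺, W⁻). The six p-values are Bonferroni-adjusted
(p_adj = min(1, 6p), α = .05). Significance stars use the conventional
bands * p<.05, ** p<.01, *** p<.001, **** p≤.0001.

## Evaluation

Leave-one-group-out: each participant is the test group once; the
cyclically next participant is the validation group (an unspecified
assignment fixed deterministically for reproducibility); metrics are
computed on windows pooled over test folds. Chewing is the positive class
for precision/recall/F1; zero denominators yield 0 with a `degenerate`
flag. A true eating segment counts as detected when strictly more than
50% of its windows (those whose center falls inside it) are predicted
chewing — the boundary case is config-switchable (`strict=False` for
≥ 50%). Predicted (post-HMM by default; raw mode available) segments
overlapping no true segment are false detections, reported with their
mean duration. False-positive rates are additionally broken down by the
majority activity of each non-eating window.

## Problem sizes

Default demo and test runs are scaled for a single CPU: the statistics
cohort is 28 participants × 5 min; the detection cohort is 6 participants
× 5 min with a 2-s slide and a 30-epoch / patience-10 / batch-64 recipe;
the quick `pipeline --small` preset uses 4 participants × 2.5 min. Chew
counting and rate recovery are validated on 50 independent 30-s segments
at 10 dB SNR.

## Known limitations

* The synthetic signals are additive and stationary within a block; real
  optomyography contains drift, posture artifacts, and cross-activity
  transitions the generator does not emulate.
* HMM smoothing assumes temporally clustered errors are rarer than
  clustered true chews; systematically misclassified long activities
  (e.g., a whole conversation) can still survive smoothing.
* Parameter counts of the reference architectures are under-determined;
  the implementations here report their own counts and make no claim of
  matching any published totals.
* The exact-Wilcoxon path is quadratic in the doubled rank total and is
  intended for cohort-scale n, not thousands of pairs.
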