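# Methods

This note documents the models, defaults, and design choices behind
`afview`, and what its tests do and do not demonstrate.

## Signal model and pre-filtering

Records hold per-lead samples in microvolts at a nominal 200 Hz with
0-based QRS sample indices and half-open `[onset, offset)` AF episode
intervals. The band-limiting pre-filter is a cascade of one first-order
Butterworth high-pass (0.5 Hz) and one first-order low-pass (40 Hz) —
a true single-section first-order band-pass does not exist, so the
stated order is applied per edge. Zero-phase (forward–backward)
application is the default: it squares the magnitude response (the 10 Hz
passband gain becomes ≈ 0.94 instead of 0.97) but introduces no group
delay, so P/f-wave positions stay aligned with the QRS annotations that
anchor the image transform. A causal mode is available via
`FilterSpec(zero_phase=False)` for streaming-like use. Annotations are
never modified by filtering. Signals are not re-quantized to the 10 µV
acquisition grid of clinical Holter hardware; amplitudes are treated as
continuous.

## Beat-stack image transform

Each beat contributes one column: the amplitude window
`[qrs − 0.75 s, qrs + 0.75 s)` — `round(1.5·fs)` samples, 300 at
200 Hz — zero-filled where it leaves the record. Columns are ordered in
time; rows run from −0.75 s (top) to +0.75 s (bottom), which puts the
central R band mid-image with the previous/next beats' R peaks above and
below. An interval with no QRS raises an explicit error rather than
emitting an empty image; full-length scans instead flag such segments
unscorable.

The colormap is a 5-anchor piecewise-linear RGB lookup table,
black (−1) → blue (−0.5) → white (0) → orange (+0.5) → red (+1), with
orange = (1, 0.65, 0). Amplitudes are clipped to a **fixed** symmetric
range (default ±2000 µV) rather than scaled per image: a fixed range is
what makes low-amplitude leads render with low contrast and
high-amplitude leads saturate, matching how such displays behave on real
recordings, and it keeps the mapping comparable across images. The
anchors and range are configurable.

Rescaling to a backbone's D × D input uses nearest-neighbor sampling
with the half-pixel-center convention (output pixel *i* reads source
index `floor((i + 0.5)·H/D)`); nearest-neighbor is stated explicitly
because resize dialects differ, and it guarantees no new colors are
invented and that the map is exactly invertible for saliency
projection. Input normalization follows each backbone's published
convention (identity, symmetric ±1 scaling, ImageNet mean/std, or
BGR-mean subtraction); the in-repo `tinycnn` takes [0, 1] values
unchanged.

## Synthetic ECG generator

The generator exists so that every downstream stage has exact ground
truth. Beats are sums of Gaussian P-Q-R-S-T waves on an RR lattice;
defaults (lead I): P 100, Q −80, R 1000, S −150, T 250 µV, with P at
−160 ms, T at +220 ms relative to the R peak. Sinus RR is
Normal(0.8 s, 0.03 s); inside AF episodes the RR process switches to a
Gamma distribution with mean 0.6 s and coefficient of variation 0.25
(shape 16), the P amplitude is set to zero, and a 60 µV fibrillatory
oscillation around 6 Hz with drifting frequency/phase is added. Lead II
is a 0.7× scaled, noisier copy (optional T-polarity flip). Noise
comprises Hanning-enveloped white-noise EMG bursts (1.5/min, 80 µV),
sinusoidal baseline wander (0.2–0.4 Hz, 100 µV), and ±1200 µV
three-sample spike artifacts (0.5/min). Each beat stores whether it was
generated by the AF process, and episode intervals are emitted verbatim
as annotations.

Cohorts derive per-record seeds from the master seed by a fixed affine
counter scheme (reproducible under parallel generation); a configurable
fraction of records receives two randomly placed AF episodes covering
roughly half the record, leaving sinus stretches before, between, and
after.

What the simulator does **not** model: waveform physiology (no dynamical
ODE model — the image transform consumes amplitude patterns only),
atrial flutter F-waves, ectopy/bigeminy, pacemakers, electrode motion
with signal loss, or inter-patient morphology variability beyond
amplitude scaling. Synthetic AF is therefore *easier* to separate than
clinical AF: passing tests demonstrate that the pipeline is wired
correctly and that the task it defines is learnable, not that clinical
accuracy figures transfer.

## Datasets

Curated sampling draws 30 s intervals uniformly over all valid
placements, strictly labeled: AF only at episode coverage 1.0, non-AF
only at 0.0; boundary-straddling intervals are excluded. Sampling is
non-overlapping by default (random placement with a deterministic
packing fallback), and counts are equalized per record and lead, so
curated datasets are exactly 50:50 by construction — a record that
cannot supply the requested count yields the achievable maximum with a
warning. Full-length monitoring cuts every sequential non-overlapping
segment, labels by majority (coverage ≥ 0.5 — the symmetric choice for
boundary segments), and keeps beat-free segments flagged unscorable.
Splits are record-disjoint at the test boundary and 70:30
train:validation within each training record; leakage is checked
programmatically.

## Classifiers and the two-phase protocol

Every classifier is a convolutional feature extractor with global
average pooling and a single sigmoid dense unit (`feature_dim + 1`
trainable head parameters). Phase 1 (**retrain**) trains only the head —
implemented on cached frozen-base features, which is mathematically
identical and much cheaper — with Adam, binary cross-entropy, lr 1e-3,
batch 64. Phase 2 (**fine-tune**) trains all non-normalization
parameters at lr 1e-5, batch 32; batch-normalization layers keep both
their scale/shift parameters and running statistics frozen, since
re-estimating statistics from a small target-domain dataset destabilizes
training. Both phases run up to 450 epochs with early stopping
(patience 20 on validation loss, chosen as a conventional value; the
protocol source does not state one) and return the checkpoint with
maximum validation accuracy at the 0.5 threshold. Training is
deterministic under the seed (CPU, float64).

The 18 named ImageNet architectures are registered with their published
input sizes and feature dimensions; nine of them (VGG16, ResNet50,
ResNet50V2, MobileNetV2 at width 0.35/1.0/1.4, DenseNet-121/-169/-201)
additionally carry exact shape-level layer tables from which parameter
counts are computed and verified against the published totals
(e.g. VGG16 14,714,688; ResNet50 23,587,712). Pretrained weights are
not bundled; the fully instantiable backbone is `tinycnn` — three conv
blocks (8/16/64 channels) with one batch-normalization layer (so freeze
logic is exercised), 64 features, default 64 px input — implemented on a
small NHWC numpy engine with hand-written backpropagation and Adam. For
a randomly initialized (non-pretrained) backbone the literature's
fine-tune rate of 1e-5 is far below what a scratch network needs, so the
desk-scale experiments use lr 1e-3 (retrain) / 3e-4 (fine-tune) and
~10–60 epochs; these were fixed once when the experiments were designed.

## Evaluation

Confusion counts use the pAF ≥ 0.5 policy; TPR/TNR/accuracy are
reported as percentages, and a rate whose class is absent is NaN with an
`*_undefined` flag, never zero (this matters when summarizing
single-class full-length segments). AUROC is the rank-based
Mann–Whitney estimator with mid-rank tie correction — numerically
identical to ROC-curve integration with fewer conventions — and is
cross-checked in tests against brute-force pair counting. Inference
cost is the median wall time over repeats normalized to the fastest
model (ratio 1.0 by construction); timing output is flagged
non-deterministic and excluded from reproducibility contracts.

The robustness suite runs five protocols: (1) test accuracy/AUROC plus
cost; (2) validation-to-test accuracy drop (inter-patient
generalization); (3) per-lead accuracies and their spread; (4) AUROC at
10/20/30 s, feeding shortened intervals to the 30 s-trained model
unchanged — a leading subinterval of a strictly labeled interval keeps
its label; (5) metrics over sequential full-length segments with
unscorable counts. Ranking marks models within ε (default 0.1
percentage points, configurable) of the best per test as top-ranked and
within ε of the worst as worst-ranked (no worst-ranks in a test whose
spread is within ε); winners maximize top-ranks subject to zero
worst-ranks. The ε-band rule reproduces the selection logic structurally
without inventing exact cutoffs, which are not published.

## Saliency

Channel importances are spatial means of `∂y_c/∂A^k` at the last
convolutional layer (resolved automatically as the last `Conv2D`;
overridable by index). The AF score is the head logit; the non-AF score
is its negation, which is the single-sigmoid equivalent of a two-output
softmax gradient. The weighted feature-map sum is rectified, bilinearly
upsampled to the input size, and max-normalized to [0, 1]; an
identically zero map is left zero (flagged) rather than divided by
zero. Gradients are validated against central finite differences
(relative error < 1e-3).

Projection onto the ECG inverts the nearest-neighbor resize to (beat,
intra-beat offset) and assigns each heatmap pixel's intensity to sample
`qrs[beat] + offset`. Overlapping beat windows combine by maximum
(preserving salient peaks; mean is available), and uncovered samples
are zero, so nonzero projected saliency always traces back to nonzero
heatmap pixels. Overlays blend the heatmap over the rescaled image with
per-pixel opacity `0.4 × intensity` and band the raw ECG trace by
projected intensity with QRS markers and the pAF caption.

## Problem sizes

Desk-scale experiments use 64 px `tinycnn` inputs and cohorts of 4–25
records of 5–20 minutes each (hundreds of training images); these sizes
were chosen so the full suite runs comfortably on a single CPU while the
statistical checks (balanced sampling, learnability AUROC ≥ 0.95,
duration ordering, RR-variability separation at ≥ 50 intervals per
class) remain well-powered.

## Known limitations

- Clinical accuracy figures cannot be reproduced without real Holter
  data and the pretrained ImageNet weights; the package validates
  structure, contracts, and desk-scale learnability instead.
- The numpy engine is CPU-only and sized for small backbones; the named
  ImageNet architectures are parameter-accounting registrations, not
  runnable models.
- Nine of the 18 registered architectures expose exact fine-tune
  parameter counts; the remainder (NASNet/Inception/Xception/
  EfficientNet families) expose head counts and input sizes only.
- QRS detection is out of scope: annotations are inputs, and the image
  geometry inherits their quality.
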