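# Methods

## Problem

Clinical sleep staging assigns each 30-second epoch of an overnight EEG one of
five AASM stages — Wake (W), N1, N2, N3 and REM.  Scorers rely on
time–frequency structure: alpha (8–13 Hz) dominating more than half an epoch
marks Wake, low-amplitude mixed-frequency activity (LAMF, 4–7 Hz) marks N1,
11–16 Hz sleep spindles (most commonly 12–14 Hz) mark N2, and high-amplitude
slow waves mark N3.  N1 is the hard class: within a single epoch it looks much
like REM, and scorers separate the two largely by context — REM rarely follows
Wake directly and rarely precedes N2, whereas N1 does both routinely.

EEGSNet operationalises this: epochs are rendered as spectrogram images, a CNN
extracts per-epoch features, and a bidirectional LSTM reads sequences of 10
consecutive epochs so that transition structure can resolve the per-epoch
ambiguity.

## Preprocessing

Each epoch, whatever its source rate (100 Hz Sleep-EDFX-style, 125 Hz
SHHS-style), becomes a fixed 76×60×3 image:

1. **Resample to 64 Hz** (polyphase, anti-aliased) — 1920 samples; the 32 Hz
   Nyquist covers every scoring band.  Upsampling is not supported.
2. **STFT**: Hann window 256, hop 128, no edge padding → 129 bins (0–32 Hz,
   0.25 Hz apart) × 14 frames; one-sided power in dB, clamped at −120 dB.
3. **Rasterize**: per-image min–max normalisation to [0,1]; separable bilinear
   resize (endpoint-aligned) to a 100-row × 80-column dot grid with row 0 =
   32 Hz; RGB lookup in a bundled 256-entry viridis table (`data/viridis_lut.csv`),
   so output depends on no plotting library.
4. **Crop** rows [14,90) and columns [11,71) → 76×60×3, the margins a figure
   canvas of that dot geometry would devote to axes and padding.

The original images were produced by a plotting library's spectrogram call and
figure rasterisation; pixel-exact reproduction of a GUI canvas is not
reproducible engineering, so this package renders the same geometry
deterministically.  Two consequences are load-bearing and tested: the image is
invariant to any positive rescaling of the input signal (log power followed by
min–max), and pure tones map back to their frequency within ±1 Hz through the
inverse of the resize/crop geometry (`frequency_of_cropped_row`).
Normalisation is per-image; per-recording normalisation would be a one-line
config alternative but is not the rendering default being emulated.

The cropped band runs ≈3.2–27.5 Hz.  Slow-wave (0.5–2 Hz) power therefore
shows only through its skirt in the lowest rows — in practice N3 remains the
easiest class to separate.

## Architecture

Five convolutional blocks, each: 3×3 stride-1 convolution (same padding) with
exact-erf GELU (x·Φ(x)), 2×2 stride-2 max pooling (ceil semantics for odd
sizes), batch normalisation, dropout with keep probability 0.5 (training
only).  Block 5 adds a 3×3 stride-1 average pooling before its normalisation.
Channel widths (16, 16, 32, 32, 64); global average pooling yields the 64-d
feature.  Two skip additions pair blocks 1→2 and 3→4.  A post-pooling output
of block 1 is half the spatial size of block 2's, so the addition is placed on
block 2's pre-pooling convolution output, where shapes match exactly; same for
3→4.  The widths are constrained by three published facts — the first
convolution has 16 kernels, the pooled feature is 64-d, and the total
trainable-parameter budget is 0.6 M — and the instantiated network lands on
628,954 parameters.

Sequence learning: 2 stacked bidirectional LSTM layers, hidden size 128 per
direction, sequence length 10; the final layer's forward and backward outputs
are concatenated (256-d) and a dense softmax predicts the five stages per
epoch.  An auxiliary dense softmax on the raw 64-d CNN features is used in
training only.  Loss:

    Loss = Loss_main + 0.5 · Loss_aux,
    Loss_main = −(1/N) Σᵢ Σₖ yₖ⁽ⁱ⁾ log p_main,ₖ⁽ⁱ⁾

with probabilities clamped to [1e−12, 1] inside the log.  Ablation variants
EEGSNet_0/1/3 change only the recurrent depth (0 layers applies the softmax
directly to each 64-d feature).

Initialisation: Glorot-uniform convolution/dense kernels, orthogonal recurrent
kernels, zero biases except the LSTM forget gates, which start at 1 — the
standard initialisation for trainable gradient flow through early recurrent
steps.  All randomness is seeded; evaluation-mode forward passes are pure
functions.

The network, its autodiff engine, and Adam are implemented directly on numpy
in `eegsnet._autodiff` / `eegsnet.nn`; gradients are verified against central
finite differences in the test suite, and the convolution is expressed as nine
shifted GEMMs for single-core throughput.

## Training and evaluation protocol

20-fold cross-validation: subject-wise where there are at least 20 subjects
(each subject's epochs in exactly one fold; with exactly 20 subjects this is
leave-one-subject-out), epoch-wise otherwise, partitioning contiguous
10-epoch sequence blocks rather than single epochs so sequence integrity is
preserved.  Each fold trains for 150 passes over its training sequences in
batches of 5 sequences, evaluates the held-out fold every 3 passes with
auxiliary head removed and dropout disabled, and keeps the best report
(highest accuracy, ties by macro-F1; the tie-break is this package's choice —
the published protocol records "the best evaluation results" without naming a
criterion).  The optimizer is likewise unspecified in the source protocol; we
use Adam (lr 1e−4 default, 1e−3 for the desk-scale runs below), gradient-norm
clip 5.0, all configurable.

Training sequences are consecutive, non-overlapping, stride 10 within a
recording; a trailing remainder shorter than 10 epochs is dropped in training
and scored in evaluation through one extra tail-aligned sequence whose
overlapping epochs are counted once.

**Batch-norm re-estimation.** Desk-scale runs take hundreds rather than
hundreds of thousands of optimiser steps, so momentum-averaged batch-norm
statistics lag the moving weights, and the lag compounds across five stacked
blocks — enough to collapse evaluation-mode predictions early in training.
Before each periodic evaluation the running buffers are therefore re-estimated
as the plain average of batch statistics over up to 8 evenly spaced training
batches under the current weights with dropout disabled (the distribution
evaluation actually sees).  This is the standard "precise BN" practice; it
changes no trained parameter and is controlled by
`TrainConfig.bn_recal_batches` (0 disables).

Metrics, from the pooled 5×5 confusion matrix (rows = reference, columns =
predicted, order W/N1/N2/N3/REM): per-class precision, recall and F1;
ACC = 100·trace/total; MF1 = unweighted mean of the unrounded per-class F1s;
Cohen's kappa = (p_o − p_e)/(1 − p_e) with p_e from the marginal products.
Zero denominators yield 0 with a warning.  The suite is cross-checked against
scikit-learn to 1e−10 on random matrices.  The released Sleep-EDFX-78 matrix
is the one published table whose printed macro-F1 (77.26) disagrees with its
own per-class F1s (mean 77.06); the package reports the recomputed value.

## Synthetic data

The generator makes the whole pipeline testable without downloads.  Each
stage has an oscillatory recipe — band-limited random-phase sinusoid combs
gated by a duty envelope plus Gaussian broadband noise:

| stage | components (band, µV amplitude, duty) | noise σ |
|-------|----------------------------------------|---------|
| W     | 8–13 Hz, 30, 0.8                       | 8       |
| N1    | 4–7 Hz, 14, 0.95                       | 8       |
| N2    | 4–10 Hz, 18, 0.9 + 2–4 spindle bursts (12–14 Hz, 0.5–1.5 s, Hann-enveloped) | 6 |
| N3    | 0.5–2 Hz, 90, 0.9                      | 10      |
| REM   | 4–7 Hz, 14, 0.95 + 7–8 Hz, 1.0, 1.0    | 8       |

Bands and duty cycles follow the scoring conventions; amplitudes and noise
levels are package constants.  N1 and REM share an identical theta core by
design: a log-scaled, min–max-normalised spectrogram makes any deterministic
recipe difference (a band edge, a duty gap) trivially visible to a CNN, which
would let a memoryless classifier solve the pair and would erase the very
phenomenon — context-dependent N1/REM disambiguation — the sequence model
exists to exploit.  REM's only within-epoch cue is a faint 7–8 Hz tail near
the broadband noise floor (a linear probe on the images separates the pair at
about 2/3 accuracy — present, but unreliable).  Per-subject amplitude gain is
drawn from [0.7, 1.4] to emulate inter-subject variability.

Hypnograms are first-order Markov chains started in Wake.  The default matrix
is a package constant whose ordinal structure follows overnight transition
statistics: P(W→N1) ≫ P(W→REM) and P(N1→N2) ≫ P(REM→N2), with strong
self-transitions.  These regularities are exactly what the Bi-LSTM can use to
resolve N1 vs REM.

What the generator does **not** emulate: K-complexes, sawtooth waves,
arousals and artifacts, stage-duration distributions beyond first-order
Markov, age or pathology effects, channel/referencing differences.  Passing
the synthetic acceptance runs therefore demonstrates that the pipeline,
model, optimiser and protocol are wired correctly and that sequence learning
captures transition structure — not that real-data benchmark accuracies are
reproduced, which requires the original recordings at GPU scale.

## Desk-scale experiment sizes

Chosen as the package's standard small-machine configuration:

- **End-to-end run**: 20 subjects × 100 epochs, 16 train / 4 test, the
  narrow `small_config` network (channels 8,8,16,16,32; hidden 64), 15 passes,
  lr 1e−3.  Reaches ≈97% held-out accuracy with seed 42 (the tested bound is
  ≥70% against 20% chance).
- **Ablation**: 10 subjects × 80 epochs, 8/2 split, a narrower variant
  (channels 4,4,8,8,16; hidden 16), 45 passes, seeds {0,1,2}.  Mean held-out
  MF1 of the 2-layer Bi-LSTM model exceeds the no-LSTM variant by ≈12 points,
  with the margin concentrated in N1 and REM, mirroring the published
  ablation's direction.

## Numerical choices and edge cases

- dB floor −120 (zero-power bins); degenerate all-equal spectrograms map to
  colormap entry 0.
- Crop indices are half-open pixel ranges ([14,90), [11,71)); epoch intervals
  are 0-based half-open [onset, onset+30).
- Max-pool ceil semantics pad with −inf and never select padding; average
  pooling normalises by the true window population at borders.
- EDF writing quantises to the 16-bit digital range over a configurable
  physical range; round-trips are exact to one quantisation step.
- Epoch containers carry float32 samples; metrics arithmetic is float64.
- `dropout_keep` is a keep probability (the two readings of "p = 0.5"
  coincide at 0.5).
- Wake-trimming before/after sleep is available (`trim_wake_minutes`) but off
  by default: all annotated epochs are kept.

## Known limitations

- The exact per-block layer counts of the original feature extractor are not
  recoverable from its description; the widths here satisfy every stated
  constraint and the parameter budget but need not be identical.
- Whether batch normalisation preceded or followed pooling in the original
  code is unstated; this package follows the listed order (pool → BN).
- The cropped frequency band excludes <3.2 Hz, so N3 is recognised by the
  slow-wave skirt rather than the band itself.
- Real-data epoch counts may differ slightly from published tallies because
  the original exclusion rules beyond movement/unscored epochs are not
  described.
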