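# eegsnet

Sleep-stage classification from single-channel EEG, via spectrogram images
and a CNN + bidirectional-LSTM sequence model.

Polysomnography is scored in 30-second epochs, each labelled Wake, N1, N2, N3
or REM (AASM).  Automatic scorers do well on most stages but fail on N1,
which within a single epoch is nearly indistinguishable from REM; human
scorers separate the two largely by context (REM rarely follows Wake or
precedes N2 — N1 does both).  EEGSNet renders each epoch as a 76×60×3
time–frequency image, extracts a 64-d feature per epoch with a five-block
residual CNN (GELU activations, global average pooling), and classifies
sequences of 10 consecutive epochs with a 2-layer bidirectional LSTM
(hidden 128 per direction) so transition structure can resolve the per-epoch
ambiguity.  Training adds an auxiliary softmax on the CNN features:

    Loss = Loss_main + 0.5 · Loss_aux,   Loss_main = −(1/N) Σᵢ Σₖ yₖ⁽ⁱ⁾ log p_main,ₖ⁽ⁱ⁾

The auxiliary head and dropout are removed at evaluation.  Evaluation uses
5×5 confusion matrices and per-class precision/recall/F1, overall accuracy,
macro-F1 (MF1) and Cohen's kappa, under 20-fold subject-wise (or, for small
cohorts, sequence-block-wise) cross-validation.

The package contains the full pipeline — EDF reading and stage mapping,
deterministic spectrogram rendering, the network (implemented directly on
numpy, with its own autodiff and Adam), the training/evaluation protocol, a
synthetic sleep-EEG generator with Markov hypnograms for desk-scale
experiments, and a CLI.  See `docs/methods.md` for the model and design
details.

## Worked example

Simulate two synthetic subjects, render spectrogram images, and inspect the
model:

```
$ eegsnet simulate --subjects 2 --epochs 20 --seed 7 --out sim
wrote 4 files to sim

$ eegsnet prepare --in sim --out images.npz
wrote 40 images of shape (76, 60, 3) to images.npz

$ eegsnet describe
block_1: Conv(16,3x3,1)+GELU+pool+BN          480
block_2: Conv(16,3x3,1)+GELU+pool+BN        2,352
block_3: Conv(32,3x3,1)+GELU+pool+BN        4,704
block_4: Conv(32,3x3,1)+GELU+pool+BN        9,312
block_5: Conv(64,3x3,1)+GELU+pool+BN       18,624
aux head: dense softmax                       325
Bi-LSTM x2 (hidden 128/dir)               591,872
main head: dense softmax                    1,285
-------------------------------------------------
total trainable parameters                628,954
                                             0.6M
```

628,954 trainable scalars ≈ 0.6 M — a lightweight model by sleep-staging
standards.  Feeding the released Sleep-EDFX-8 benchmark confusion matrix
(bundled with the package) to the metrics suite:

```
$ eegsnet metrics --confusion table3.csv
ACC 94.17
MF1 87.78
Kappa 0.91
W    PR  99.06  RE  99.09  F1  99.08
N1   PR  76.53  RE  64.77  F1  70.16
N2   PR  91.04  RE  90.32  F1  90.68
N3   PR  82.77  RE  91.69  F1  87.00
REM  PR  92.68  RE  91.33  F1  92.00
```

ACC is the diagonal fraction of the matrix (94.17% of 15,000 scored epochs),
MF1 the unweighted mean of the five per-class F1s, and kappa the
chance-corrected agreement between model and specialists.  N1 is, as always,
the weakest class; 70.16 is nevertheless high for it, the gain the sequence
model's transition learning delivers.

Training on your own data: convert EDF + hypnogram pairs with `prepare`,
then `eegsnet train --config cfg.yaml` (YAML selects the image container,
cross-validation mode, and any `TrainConfig`/`ModelConfig` overrides; every
run writes a manifest with config, seed and version).

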