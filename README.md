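# emgsel

EMG feature/channel selection and classifier evaluation for hand-posture
recognition across wrist positions.

Pattern-recognition control of partial-hand prostheses must classify hand
postures (rest, hand open, key grip, chuck grip) from multi-channel surface
EMG while the user moves their wrist — and wrist posture strongly modulates
the forearm (extrinsic) muscle signals that such systems rely on.  `emgsel`
is a library for the offline analyses this problem calls for: which
classifier, which features from which channels, and how many wrist
positions training data must cover.  It is aimed at myoelectric-control and
biosignal-processing researchers who want a tested, reproducible
implementation of the full pipeline, driven either by their own recordings
(plain-text trial files + manifest) or by the built-in synthetic generator.

## What it implements

- **Synthetic EMG generator** (`emgsel.synth`): amplitude-modulated,
  band-limited (30–350 Hz Chebyshev type-I) Gaussian noise at 1000 Hz;
  motion class encoded as a spatial gain pattern, wrist position as
  low-rank multiplicative modulation applied predominantly to extrinsic
  channels, per-repetition contraction-effort jitter; "intact-like" and
  "amputee-like" presets; full protocol (4 postures × 7 positions ×
  repetitions × 3-s trials), deterministic under a seed.
- **Features** (`emgsel.features`): 25 per channel — MAV, ZC, SSC, WL,
  WAMP, RMS, VAR, v-order(3), log-detector, AR1–AR6 (Burg), MnF, MdF, PF,
  MP (Hamming periodogram), and the six time-domain power-spectrum
  descriptors PSD1–PSD6 — extracted from 200 ms windows at a 20 ms frame
  increment.
- **Separability filter** (`emgsel.separability`): per feature/channel
  column, the separability index

      SI = min over class pairs (cX, cY) of D_B{cX, cY}

  with D_B the univariate Gaussian Bhattacharyya distance; the SI feature
  set keeps the top 10 × n_channels columns.
- **Wrapper selection** (`emgsel.selection`): sequential forward search
  with an LDA wrapper (two-fold error objective), PCA ordering,
  error-vs-feature-count curves, the 99%-decrease reduced set X, and
  per-feature selection frequencies.
- **Classifiers** (`emgsel.classifiers`, `emgsel.nn`): LDA, QDA (shrinkage
  regularised), and two single-hidden-layer networks — LNN (4 linear
  units) and MLPANN (7 tanh units) — trained by scaled conjugate gradient
  with validation-based early stopping.
- **Evaluation** (`emgsel.evaluation`): the 50/30/20 two-fold swap scheme
  (window- or repetition-level assignment), per-condition reports with
  confusion matrices, sensitivity/specificity, and the exhaustive
  wrist-position combination search.

A thin CLI (`emgsel generate|extract|rank-si|select|train|evaluate|run`)
wires the stages together for shell use; `examples/` holds one short
narrative script per capability.

## Worked example

Comparing the four classifiers on a synthetic intact-like subject (3
extrinsic + 2 intrinsic channels, TDAR features, all seven wrist positions,
two-fold 50/30/20 scheme — `examples/04_classifier_comparison.py`):

```
1680 windows x 50 TDAR features; fold-1 train/test/val = 840/504/336

classifier   error%   sensitivity   specificity
  LDA         1.09      0.989         0.996
  QDA         4.37      0.956         0.985
  LNN         1.09      0.989         0.996
  MLPANN      1.19      0.988         0.996
```

The linear models and the tanh MLP are equivalent within noise; the QDA,
which estimates a separate covariance per class from the same data, is
measurably worse — the small-sample penalty of its extra parameters.

Feature-set comparison on an amputee-like subject
(`examples/05_feature_selection.py`):

```
feature set    two-fold LDA error%
  all (75)     30.77
  TDAR (30)    29.74
  TD (12)      29.50
  SI (30)      30.42
  SFS (30)     27.42

SFS error-vs-count: e(1) = 34.24%, min = 27.26% at k = 22
99%-decrease rule: X = 11 features already capture 99% of the drop
```

The wrapper-selected set beats every fixed set of the same (or larger)
size, and the 99% rule shows a third of the columns already deliver the
full benefit.  The wrist-position analysis
(`examples/06_wrist_positions.py`) completes the picture: training on one
wrist position gives 26.8% error on all-position testing, two to four
positions recover most of the loss (20.3%), and further positions add
nothing.

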