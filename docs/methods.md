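# Methods

`emgsel` implements an offline evaluation pipeline for myoelectric
hand-posture recognition across wrist positions: a synthetic surface-EMG
generator, a 25-feature-per-channel extractor, a Bhattacharyya-distance
separability filter, an LDA-wrapped sequential forward search, four
classifiers, and the two-fold evaluation protocols (including the
wrist-position combination search).  This note records the models, the
defaults and why they are what they are, and the choices made where the
design was genuinely open.

## Synthetic EMG model

Surface EMG during a steady, submaximal isometric contraction is modelled
as amplitude-modulated, band-limited Gaussian noise.  Channel `c` of a
trial with motion class `k`, wrist position `p` and repetition `r` is

    x_c(t) = ( G[k,c] · M[p,c] · E[r,c] + floor ) · n_c(t)

with

- `n_c(t)` — independent unit-RMS noise per channel: white Gaussian noise
  shaped by a zero-phase Chebyshev type-I band-pass (30–350 Hz, 0.5 dB
  ripple, order-8 low-pass prototype, i.e. a 16-pole band-pass — the MATLAB
  `cheby1(8, Rp, Wn)` convention) and rescaled by the filter's white-noise
  RMS gain.  At 1000 Hz sampling the in-band/out-of-band power ratio is
  ≈ 120–135 (≥ 20 dB) and the in-band spectrum is flat within ±1 dB.
- `G[k,c]` — class activation gains.  The rest row is exactly zero (rest is
  noise-floor only); active-class gains are `exp(class_sep · u[k,c])` with
  fixed `u ~ U(−1,1)` drawn once from a structural constant, so class
  identity is a *spatial amplitude pattern* and `class_sep` controls how far
  apart the three grasp patterns lie.
- `M[p,c]` — wrist-position modulation, `exp(spread_c · v[p,c])`.  The
  direction matrix `v` is **rank-2** (2 position weights × 2 channel
  patterns, normalised to [−1,1], neutral row zero): wrist posture rescales
  muscle activity along a small number of fixed spatial patterns rather
  than independently per channel.  The low rank is what makes the position
  effect learnable — a classifier trained on several positions can discount
  those directions, while one trained on a single position cannot; with
  i.i.d. per-(position, channel) directions the effect is statistically
  white and multi-position training buys nothing, which contradicts the
  phenomenon being modelled.  `spread_c` is `extrinsic_position_spread` for
  forearm channels and the (strictly smaller) `intrinsic_position_spread`
  for hand channels, encoding that intrinsic muscles do not cross the wrist.
- `E[r,c] = exp(jitter · z)` — per-repetition, per-channel log-normal
  contraction-effort variability (`z ~ N(0,1)` from the trial's substream).
  Without it the generator is Bayes-separable with enormous margins and
  every classifier scores exactly 0%, which reproduces none of the study's
  trends; repeat-contraction amplitude variability of 15–25% CoV is
  standard surface-EMG phenomenology.
- `floor` — a baseline amplitude on every channel regardless of class.

An optional per-class **spectral tilt** (`spectral_tilt`) multiplies the
in-band power density by `(f/f_geo)^a_k`; it is off in both presets, so by
default all classes share one spectrum and scale-invariant features carry
no class information.  (Enabling it makes AR and spectral features
class-informative and position-robust simultaneously, which equalises the
TDAR and SFS sets; the presets keep the class code amplitude-only so the
feature-set comparison retains its structure.)

### Presets

| parameter                  | intact-like | amputee-like |
|----------------------------|-------------|--------------|
| class_sep                  | 0.5         | 0.4          |
| extrinsic_position_spread  | 0.25        | 0.8          |
| intrinsic_position_spread  | 0.08        | 0.15         |
| repetition_jitter          | 0.15        | 0.25         |
| noise_floor                | 0.05        | 0.08         |

Both presets follow the full protocol: 4 postures × 7 wrist positions ×
`repetitions` (default 10; 4 for the short protocol variant) × 3-s trials.
Magnitudes were calibrated once so that the presets land in realistic error
ranges (low single digits for intact-like with combined muscles, ~15–30%
for amputee-like) and reproduce the qualitative trends — they claim no
subject-level fidelity.  The generator deliberately omits motor-unit
structure (MUAP trains, conduction velocity), electrode shift, fatigue
drift, and any posture-transition dynamics (trials are steady-state by
construction); passing tests therefore demonstrate correctness of the
analysis pipeline and reproduction of the amplitude-driven mechanisms, not
performance on real recordings.

### Determinism

Each trial draws from `default_rng(SeedSequence(seed, spawn_key=(crc32("class|position|rep"),)))`,
so datasets are reproducible bit-for-bit and independent of generation
order.  The gain/modulation *structure* (the `u`, `v` draws) comes from a
fixed structural constant and is part of the preset definition, not of a
dataset's randomness.

## Features (25 per channel)

| family    | features                 | notes |
|-----------|--------------------------|-------|
| TD        | MAV, ZC, SSC, WL         | Hudgins set; ZC/SSC use an amplitude threshold |
| amplitude | WAMP, RMS, VAR, Vord, LogDet | VAR unbiased; Vord order 3; LogDet guard δ=1e−10 |
| AR        | AR1–AR6                  | Burg's method on the mean-removed window |
| spectral  | MnF, MdF, PF, MP         | Hamming-tapered periodogram |
| PSD       | PSD1–PSD6                | time-domain power-spectrum descriptors |

Choices that the problem statement leaves open:

- **Thresholds.**  ZC, SSC and WAMP use one per-channel threshold,
  `0.01 × pooled channel standard deviation` over all windows of the
  extraction run, frozen for the run and recorded in the feature-matrix
  header.  Scale-aware, reproducible, conventional in the EMG literature.
  WAMP uses a strict inequality so a constant signal scores 0 even at zero
  threshold.
- **AR estimation.**  Burg's method (stable on 200-sample windows),
  vectorised across windows; coefficients are reported in the regression
  convention `x_t = a1 x_{t−1} + …` and exclude the innovation variance.
  The implementation is cross-checked against `statsmodels`' Burg routine
  to machine precision in the test suite.  Zero-variance windows fall back
  to all-zero coefficients with a `FeatureWarning`.
- **Spectral estimation.**  A single Hamming-tapered periodogram of the
  whole window, FFT length = next power of two (minimum 256).  MnF is the
  spectral centroid, MdF the smallest frequency reaching half the total
  power, PF the argmax excluding the DC bin, MP the mean over bins.
  All-zero windows return zeros with a warning.
- **TD-PSD.**  Spectral moments are computed in the time domain via
  Parseval — `m0 = ‖y‖₂`, `m2 = ‖Δy‖₂/(n−1)`, `m4 = ‖Δ²y‖₂/(n−1)` — each
  power-compressed by `m ← m^λ/λ` with λ = 0.1.  The `(n−1)` normalisation
  of the difference moments keeps `m0 − m2` and `m0 − m4` positive for
  band-limited signals (for in-band EMG `‖Δy‖₂ > ‖y‖₂`, so the
  unnormalised moments would make those logs degenerate on essentially
  every window).  Six log-domain descriptors (log m0, log(m0−m2),
  log(m0−m4), sparseness, irregularity factor, waveform-length ratio) are
  computed on the record (`a`) and on its element-wise square (`b`, the
  non-linear mapping), and combined as the orientation
  `PSDk = −2 a_k b_k/(a_k² + b_k²) ∈ [−1, 1]`.  Non-positive log arguments
  are guarded at 1e−12 with a warning; the output is clipped to [−1,1]
  against float rounding at the bound.

Feature matrices are windows × (channel, feature) with channel-major column
order; extraction raises on any non-finite value, naming the window and
column.

## Separability index

Per column, `SI = min over class pairs of D_B`, with the univariate
Gaussian Bhattacharyya distance

    D_B = ¼ (μa − μb)²/(σa² + σb²) + ½ ln[ (σa² + σb²)/(2 σa σb) ]

estimated from sample means and unbiased variances, pooled over all wrist
positions.  The Gaussian parametric form is a package choice (the density
assumption is not dictated); a variance floor of `1e−12 × pooled variance`
(with an absolute floor for exactly constant data) guards degenerate
columns — a perfectly class-coded constant column correctly diverges.
Ranking ties break by the fixed channel-then-catalog column order.  The SI
feature set keeps the top `10 × n_channels` columns, the TDAR-set size.

## Classifiers

- **LDA/QDA** — Gaussian discriminants with empirical priors; LDA pools the
  within-class covariance (divisor N − K), QDA estimates one per class.
  Singular covariances are shrunk toward `(tr Σ/d)·I`, with the shrinkage
  weight escalated from 0 in steps of 1e−4 until a Cholesky factorisation
  succeeds.  Prediction is argmax of the Gaussian log posterior, ties to
  the lowest class index.
- **LNN / MLPANN** — one hidden layer of 4 linear / 7 tanh units, softmax
  output (one unit per class) with cross-entropy loss.  The linear-hidden
  LNN is algebraically a single affine classifier (the tests assert the
  collapsed form exactly).  The softmax output and cross-entropy loss are
  package choices; inputs are z-scored with training-partition statistics
  (SCG convergence is poor on raw heterogeneous feature scales).
- **Training** — full-batch scaled conjugate gradient (Møller's algorithm;
  one SCG step per epoch), max 300 epochs, validation classification error
  checked every epoch with patience 6, best-validation weights restored.
  Deterministic under the training seed.

## Evaluation protocols

- **Two-fold 50/30/20 swap.**  Within every class × position cell, units
  are shuffled and split 50% train / 30% test / 20% validation (fold 1);
  fold 2 trains on fold 1's test∪validation and re-divides fold 1's
  training portion 60/40 into its test and validation parts (which 30% of
  the old training data becomes fold-2 test is random under the scheme
  seed).  Reported errors are the two-fold average; confusion matrices
  accumulate over both folds.  Every cell must contain ≥ 10 units.
- **Assignment unit.**  `window` (the literal reading of "% of all data")
  or `repetition`.  Overlapping 200 ms/20 ms windows from one repetition
  are nearly duplicates, so window-level splits leak heavily and drive
  errors toward zero; repetition-level splits are leakage-free.  Both are
  first-class; the trend analyses in the tests use the repetition unit.
- **Wrist-position search.**  For each of the C(7,n) position subsets, the
  training (and validation) rows of each fold are restricted to the subset
  positions while the test rows keep all seven positions; the minimum-error
  combination is reported per n.  The min over combinations is optimistic
  for small n (selection on the same test partitions), which matches the
  original procedure; the curve's tail can therefore tick up slightly at
  large n.
- **Sensitivity / specificity.**  From the pooled 4×4 confusion matrix:
  sensitivity = Σ diagonal / Σ all; specificity = macro average over
  classes of TN/(TN+FP) (one-vs-rest).  With balanced classes sensitivity
  equals 1 − error exactly.

## Feature selection

- **SFS** keeps set A (selected) and set B (candidates); each step adds the
  candidate whose *joint* LDA error with A is minimal, stopping at
  `K = 10 × n_channels`.  The wrapper objective is the **two-fold average
  error of the standard scheme** — the same quantity the finished sets are
  compared on.  A single-fold objective was tried and rejected: it makes
  the greedy search noticeably noisier without being cheaper in any way
  that matters, because the LDA for a candidate subset is fitted from
  pre-accumulated class means and pooled scatter (sub-block selection is
  algebraically identical to refitting, which the oracle tests verify by
  exhaustive enumeration).  Ties break to the lowest column index.
- **PCA ordering** z-scores columns with fold-training statistics, fits the
  rotation on the fold's training partition, truncates to numerical rank,
  and adds components in explained-variance order.
- **Error-vs-count curves** report the two-fold LDA error of the first k
  columns of an ordering; they are not forced monotone (held-out error can
  rise as features are added).
- **99%-decrease rule.**  `X = min{ k : e1 − ek ≥ 0.99 (e1 − e_min) }` with
  `e_min` the global minimum of the trajectory (the alternative reading,
  e_min = final-K error, is not used); a flat trajectory gives X = 1.
- **Selection frequency.**  Per subject, a feature's probability is the
  fraction of channels whose (channel, feature) column is among the first X
  selected; probabilities are averaged across subjects with the
  across-subject standard error (0 for a single subject).

## Problem sizes

The test suite and the acceptance script run the pipeline at reduced
montage sizes chosen to keep the full run in minutes on one core while
preserving every structural property: 2–5 extrinsic + 1–2 intrinsic
channels for pipeline analyses (the structural-conformance checks use the
full 9 + 4 montage), 4–10 repetitions, and 100–200 ms frame increments for
the trend analyses (the 20 ms protocol increment is used where window
density itself matters).  Directional trends (wrist-position curve, SFS vs
TD/TDAR, QDA vs LDA) are asserted over 10 generator seeds with a two-sided
sign test at level 0.05.

## Known limitations

- Class information in the presets is purely spatial/amplitude; any
  conclusion about the *relative* merit of specific spectral features on
  real EMG is outside what the synthetic data can support.
- The QDA-vs-LDA gap appears only when training data is scarce relative to
  dimensionality, as in the study; with abundant data both reach the same
  (near-zero) error on the presets.
- Window-level splits are provided for protocol fidelity but are
  optimistically biased; repetition-level numbers are the ones to trust.
- The SCG implementation is full-batch and CPU-only, adequate for the
  feature dimensionalities here (≤ a few hundred inputs).
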