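# Methods

`nirhsi` implements an analysis pipeline for near-infrared hyperspectral
(NIR-HSI) images of tissue cores: preprocessing, unsupervised
convolutional-autoencoder feature learning, consensus outlier quality
control, leave-one-out neural classification, and unsupervised
structure/interpretability analysis. Because the tissue dataset the
pipeline was designed around is not publicly deposited, the package
ships a synthetic phantom generator that emulates the acquisition, so
every stage is exercised end to end by generated data.

## Data model and preprocessing

A sample is a rank-3 cube `(rows, cols, bands)` with a strictly
increasing wavelength vector in the NIR window (1000–1750 nm). Two
preprocessing steps are applied per cube, in this order:

1. **Min-max scaling** of all voxels to [0, 1]. The scaling is per cube
   (not per band): the motivating artifact is cube-wide illumination and
   detector gain. A constant cube maps to all zeros; this keeps the
   range contract without dividing by zero.
2. **SD clipping** at mean ± 5 SD, pooled over all voxels, suppressing
   extreme spectra from measurement artifacts while leaving in-band
   voxels bit-identical. A per-spectrum variant (`scope="pixel"`) is
   provided because the pooling convention is a genuine design choice;
   the pooled form is the default.

The band count is data-driven throughout — nothing hard-codes the
full-resolution 750-band acquisition, and the test suite runs on 8–16
band cubes.

## Phantom generator

Each synthetic core is built as

```
cube = baseline(b) * texture(r, c) * illumination(r, c) + signal + noise
```

* `baseline`: sum of three broad Gaussian bumps over the band axis with
  ±2 % per-sample amplitude jitter, mimicking overlapping overtone bands
  of water, lipids and proteins;
* `texture`: a randomized rotated ellipse (the tissue core / lesion
  region, axes 28–40 % of the image) at intensity 1 with smooth Gaussian
  blob texture (SD 0.15), against a dim background (0.25);
* `illumination`: a zero-mean multiplicative tilt plane with maximum
  relative amplitude `illumination_gradient` (default 0.2);
* `signal`: cancer cubes only — `effect_size * noise_sd` added at two
  fixed signature bands (Gaussian profile over neighboring bands),
  inside the lesion ellipse. Adding the term after the multiplicative
  factors makes the class-mean separation at signature bands exactly
  `effect_size * noise_sd`, which the tests verify by Monte Carlo;
* `noise`: i.i.d. Gaussian, SD `noise_sd` (default 0.05).

Defaults emulate the study cohort: 78 samples, cancer fraction 0.5 (the
source cohort's class split is not published; a balanced split is the
neutral choice), 64×64×16 cubes. The spatial/spectral size is a
deliberate desk-scale reduction of the 600×450×750 acquisition chosen so
a full multi-seed analysis runs in minutes on one CPU; nothing in the
code depends on the reduction.

Planted outliers emulate preparation/measurement faults: a global gain
`×(1 + severity)` plus additive spikes of `severity × SD` at three
random bands. The spike amplitude uses the corrupted cube's own SD so
that the planted severity survives per-cube min-max renormalization —
with the pre-gain SD the preprocessing would silently divide the
severity by `(1 + severity)`. Randomness is fanned out per sample from
one cohort seed (`SeedSequence.spawn`), so cohorts are bit-reproducible
and extendable.

**What the phantom does not model:** realistic histological morphology,
scattering/radiative-transfer physics, spatially correlated noise,
instrument wavelength calibration error, or batch effects. Passing tests
demonstrate that the pipeline recovers the signals the generator plants
under controlled conditions — not clinical performance on real tissue.

## Feature learning

Overlapping 5×5 spectral patches are tiled with stride 2 (the stride is
a free parameter; 2 keeps overlap while bounding patch counts on
full-resolution cubes). The autoencoder's encoder applies two valid
convolution blocks (3×3×3 kernels spanning both spatial axes and the
band axis when the cube has ≥ 8 bands, otherwise 3×3 with bands as
channels; filters 8→16, batch normalization, ReLU), then dropout (0.1)
and a dense bottleneck of `d = 128` latent units. The decoder is a dense
mirror back to the patch shape. Training minimizes mean-squared
reconstruction error with Adam (lr 1e-3, cosine-annealed), batch 256, up
to a configurable number of epochs with plateau early stopping; the
best-epoch parameters are restored. The training pool is a uniform
random subsample of the cohort's patches (default cap 6000) — patch
statistics are highly redundant across overlapping tiles, and the cap
makes training time independent of cohort size.

Each sample's patch embeddings are aggregated into one global feature
vector by concatenating four per-dimension statistics in fixed order:
mean, maximum, population SD (ddof 0), and IQR with linear-interpolation
quantiles — `4 d = 512` features. Aggregation is permutation-invariant
in the patches and is what the outlier detectors and classifier consume.

Two descriptions of the aggregated representation circulate (a 128-D
pooled vector vs. the concatenation of four statistics); the
concatenation is implemented because it is the one defined operationally,
and the mean block alone reproduces the pooled variant.

## Outlier quality control

Five detectors vote per sample on the global features:

| method | statistic | flag rule (default) |
|---|---|---|
| Z-score | max over features of abs. z | > 3 |
| IQR | fraction of features outside Tukey fences (k = 1.5) | > 0.10 |
| Mahalanobis | d² in 10-D PCA space, robust shrinkage covariance | > χ²₀.₉₉₉ |
| Isolation Forest | anomaly score rank (100 trees, seeded) | lowest round(0.1 n) |
| LOF | local outlier factor rank (k = 20, capped n−1) | highest round(0.1 n) |

Thresholds are calibrated so each method flags roughly 10 % of a cohort,
keeping the 3-of-5 consensus selective; all are tunable and echoed into
the report. Consensus categories: **strong** (≥ 3 votes, removed),
**moderate** (exactly 2, reported for manual review, never
auto-removed), **normal** (≤ 1).

Because there are `4d = 512` features and only tens of samples, the
Mahalanobis detector always works in a PCA-reduced space
(`q = min(10, n−2)`), and its center/scatter are estimated robustly
(minimum covariance determinant) before shrinking 10 % toward the
spherical target. The robust estimate matters: with ~11 % gross
outliers, a non-robust covariance is inflated along each outlier's own
direction, bounding that outlier's d² near the χ² cutoff (masking); the
MCD estimate removes this failure mode. The non-robust Ledoit–Wolf path
is retained (`robust=False`).

## Classification

A configurable fully connected network maps standardized global features
through optional train-time input noise (SD 0.05), an optional softmax
attention gate, hidden blocks (dense + batch norm + ReLU/ELU/GELU +
dropout), and a 2-way softmax. Training uses class-weighted
cross-entropy (inverse-frequency weights normalized to mean 1) with
label smoothing 0.1, gradient clipping at global norm 1.0, AdamW
(weight decay 0.01) with cosine annealing to 1 % of the initial rate,
and early stopping on the training-loss plateau — no validation split
exists inside a leave-one-out fold. The feature scaler is fit inside
`train_classifier` on the training data only and replayed at prediction,
so cross-validation cannot leak test statistics; the LOOCV audit log
records the per-fold scaler provenance. Prediction ties at probability
0.5 go to class 0 (arbitrary but fixed).

The default configuration is the best found by the refined search:
single 512-unit hidden layer, ELU, dropout 0.4, AdamW at lr 0.001, 20
epochs. The random search samples from the refined space (hidden
512–1024 step 128 or 768-384-192; dropout U[0.4, 0.6]; lr U[5e-4, 1e-3];
ELU fixed) or a broader space that also varies the activation, and
scores each trial by LOOCV balanced accuracy.

The attention mechanism is deliberately simple — one softmax gate over
input features applied multiplicatively (scaled by the feature count so
a uniform gate is the identity). Its weights are directly interpretable
per feature, and because each global feature block maps back to a latent
dimension, attention can be projected onto the patch grid: each patch
scores the attention-weighted L1 norm of its embedding, normalized to
[0, 1] and upsampled nearest-neighbor to the cube size. Attention is off
by default for accuracy runs and on for map generation.

## Evaluation

Leave-one-out cross-validation: n folds, each training on n−1 samples
and predicting the held-out one; deterministic per-fold seeds. Headline
metric is balanced accuracy (unweighted mean of per-class recalls),
with per-class precision/recall/F1 and the confusion matrix. A fold
whose training partition loses a class is recorded as degenerate and
predicted by majority vote with a warning.

Autoencoder scope: the pipeline's default (`feature_mode: "global"`)
fits the autoencoder once, unsupervised, on the whole cohort — the
procedure the study design describes. This shares unlabeled structure
across folds; a strictly leakage-free `per_fold` mode that refits the
autoencoder on each fold's training cubes is implemented and tested, but
costs n autoencoder fits and is disproportionate at default problem
sizes. Both modes are recorded in the run record.

## Clustering and visualization

Sample-level K-means scans k = 2..10 (10 restarts, best inertia kept),
reporting silhouette per k; run-to-run stability is the mean pairwise
adjusted Rand index over 20 seeded restarts; agreement with tissue
labels uses ARI at k = 2. Pixel-level cluster maps cluster a cube's
patch embeddings (k = 5 by default) and paint the patch grid, upsampled
nearest-neighbor — no smoothing, so cluster boundaries stay faithful.
Silhouette on pixel-level clusterings subsamples at most 5000 patches
with a logged seed. False-color composites render bands (2, 0, 1)
weighted (1.0, 0.8, 1.0), each band min-max normalized per channel; a
constant band renders at its full weight level.

## Numerical choices

* Network arithmetic is float32; losses are accumulated in float64.
* All randomness flows from explicit `numpy.random.Generator` streams;
  the pipeline derives per-stage seeds as `SeedSequence((seed,
  crc32(stage_name)))`, so stages rerun independently yet reproducibly.
* Ensemble detectors (Isolation Forest, LOF) flag exactly
  `round(contamination × n)` samples by score rank, ties broken by
  sample order — exact flag counts are part of the contract.
* Population SD (ddof 0) and linear-interpolation quantiles everywhere a
  spread statistic appears; both conventions are asserted by tests.
* Batch normalization uses running statistics at prediction; dropout and
  input noise are train-time only, so repeated predictions are
  bit-identical.

## Problem sizes used by the test suite and acceptance script

The multi-seed checks run on reduced cohorts chosen as the package's
own desk-scale defaults: outlier recovery on 78-sample cohorts of
32×32×12 cubes (10 seeds); classification signal recovery on 60-sample
cohorts of 64×64×16 cubes (5 seeds, LOOCV per cohort); stability on a
30-sample cohort. These sizes preserve every structural property of the
full-scale analysis (patch overlap, 512-D features, fold counts) while
keeping a complete run in the minutes range on one CPU.

## Known limitations

* The numpy neural-net core implements exactly the layers this pipeline
  needs; it is not a general deep-learning framework (no GPU, no
  autograd graph).
* The phantom's outlier mechanism (gain + band spikes) is one of many
  plausible artifact models; detectors tuned here may need re-tuning on
  real acquisitions.
* Reported accuracies on phantoms say nothing about accuracy on real
  tissue; the study's real-data numbers are not reproducible without the
  undeposited dataset and are not targets of the test suite.
* The 2-D convolution fallback for cubes with < 8 bands shares code but
  not weights with the 3-D path; models are not portable across band
  counts.
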