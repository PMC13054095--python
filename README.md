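# nirhsi

Analysis pipeline for near-infrared hyperspectral (NIR-HSI) images of
tissue cores, aimed at distinguishing cancerous from non-cancerous
pancreatic tissue without staining. NIR spectra (1000–1750 nm) respond
to overtone vibrations of water, lipids and proteins, so each spatial
pixel of a hyperspectral cube carries a chemical fingerprint of the
tissue; the pipeline turns a cohort of such cubes into calibrated
classification results and interpretable maps.

The package is written for researchers working with small labeled
cohorts (tens of samples, e.g. a tissue microarray), where data quality
control and leakage-free evaluation matter as much as the model.

## What it does

1. **Preprocessing** — per-cube min-max scaling to [0, 1], then clipping
   at mean ± 5 SD to suppress measurement artifacts.
2. **Feature learning** — overlapping 5×5 spectral patches are encoded
   by a convolutional autoencoder (3-D kernels over space and
   wavelength, 128-D bottleneck) trained by L2 reconstruction; each
   sample's patch embeddings are aggregated into a 512-D global feature
   vector `[mean | max | SD | IQR]`.
3. **Consensus outlier QC** — five detectors (Z-score, Tukey IQR,
   robust Mahalanobis in PCA space, Isolation Forest, LOF) vote per
   sample; samples flagged by ≥ 3 methods are *strong consensus
   outliers* and removed, exactly 2 votes marks *moderate* outliers for
   manual review.
4. **Classification** — a configurable fully connected network (default:
   one 512-unit hidden layer, ELU, dropout 0.4, AdamW, label smoothing,
   balanced class weights, gradient clipping, cosine annealing),
   evaluated by leave-one-out cross-validation with balanced accuracy

   `BA = (recall₀ + recall₁) / 2`

   plus per-class precision/recall/F1. A refined random search over
   hidden sizes 512–1024 / 768-384-192, dropout 0.4–0.6 and lr
   5e-4–1e-3 is built in.
5. **Structure & interpretability** — K-means scans (k = 2..10) with
   silhouette, run-to-run stability as mean pairwise adjusted Rand
   index, pixel-level cluster maps (k = 5), false-color band composites
   (bands 2, 0, 1 weighted 1.0, 0.8, 1.0), and neural attention maps.

Because the original tissue dataset is not deposited, the package
includes a first-class **phantom generator** that emulates the 78-core
microarray: class-dependent smooth NIR signatures, elliptical
lesion/parenchyma geometry, illumination gradients, noise, and planted
outlier samples with known ground truth. All tests and the acceptance
script run against phantoms.

## Worked example

```python
from nirhsi import (
    PhantomConfig, generate_cohort, preprocess, detect_outliers,
    ClassifierConfig, loocv,
)
from nirhsi.pipeline import extract_cohort_features

# a 20-sample phantom cohort with 2 planted outlier samples
cfg = PhantomConfig(n_samples=20, height=32, width=32, bands=12,
                    effect_size=6.0, n_outliers=2, seed=42)
cubes, labels = generate_cohort(cfg)
cubes = [preprocess(c) for c in cubes]

feats, model, embeddings = extract_cohort_features(cubes, epochs=10,
                                                   max_train_patches=2000,
                                                   seed=0)
print(feats.shape)

report = detect_outliers(feats, seed=0)
print(report.strong_ids)

keep = [i for i, c in enumerate(cubes) if c.sample_id not in report.strong_ids]
cv = loocv(feats.iloc[keep], labels[keep], ClassifierConfig(seed=0))
print(f"balanced accuracy {cv.balanced_accuracy:.3f} over {len(cv.folds)} folds")
```

prints

```
(20, 512)
['S007', 'S016']
balanced accuracy 1.000 over 18 folds
```

— the feature table is 20 samples × 512 global features; the consensus
correctly isolates the two planted outliers; and leave-one-out
classification of the cleaned cohort separates the classes perfectly at
this effect size (6 noise-SD units of spectral separation).

The same workflow runs from the shell:

```bash
nirhsi phantom generate --config phantom.yaml --out cohort/
nirhsi features extract --manifest cohort/manifest.csv --out features.csv
nirhsi outliers detect --features features.csv --out report.json
nirhsi run --config pipeline.yaml --seed 0 --out run/
```

`nirhsi run` executes the full workflow (phantom or manifest cohort) and
writes a run record with every stage's parameters, artifact checksums
and wall times; identical config + seed reproduces identical artifacts
bit for bit.

## Layout

```
src/nirhsi/
  cube_io.py      cubes, TIFF/npz I/O, manifests, preprocessing
  phantom.py      synthetic tissue-microarray generator
  features.py     patches, conv autoencoder, global features
  outliers.py     five detectors + consensus report
  classifier.py   configurable NN, attention, hyperparameter search
  evaluation.py   LOOCV harness and metrics
  clustering.py   K-means scans, stability, ARI, image products
  pipeline.py     one-command orchestration with seeded substreams
  cli.py          click CLI (`nirhsi ...`)
```
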