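# rhizospec

Hyperspectral NIR root-phenotyping pipeline: from raw push-broom reflectance
cubes to segmented, measured root systems and chemometric root analysis.

The package covers the full workflow for rhizobox imaging in the 900–1700 nm
range:

- **`hypercube`** — ENVI cube I/O, white/dark normalization
  (`N = (R − D)/(W − D)`), band trimming to 1000–1700 nm, dead-pixel/spike
  masking from the difference-spectrum standard deviation.
- **`pretreat`** — the 2 × 4 × 2 factorial pre-treatment bank:
  {none, log(1/R)} × {none, 2nd-order polynomial de-trend, Savitzky–Golay 1st
  derivative, asymmetric-least-squares (ALS) baseline} × {none, SNV}.
  MSC is available as an optional extra.
- **`bandselect`** — pre-treatment and wavelength scoring: six non-Gaussian
  indicators (skewness, kurtosis, entropy, negentropy, SNR, KL divergence)
  with average-rank aggregation, Bhattacharyya distance on root/soil ROI
  histograms for single wavelengths and difference spectra, top-10 band
  selection by nomination frequency, and dimensionality reduction
  (best band, 10-band mean, 10-band stack, PCA).
- **`segment`** — multilevel Otsu thresholding, k-means, fuzzy c-means and a
  two-class SVM, with a quality gate on binary-image skewness (< 2.5 fails).
- **`postprocess`** — Fourier-domain phase-correlation stitching of
  overlapping scan strides, small-object noise filtering, and skeleton-based
  root-length estimation (orthogonal steps + √2-weighted diagonal steps).
- **`chemometrics`** — eight radial tissue classes from distance to the root
  medial axis, a one-vs-one ECOC decision-tree classifier on ALS-corrected
  spectra reduced to 5 principal components, and exponential root-decay
  modelling (`t = a·exp(b·x)`) with Bhattacharyya-based decay-feature
  selection.
- **`synthscene`** — seeded synthetic rhizobox scenes with full ground truth
  (root mask, skeleton length, tissue map, decay parameters, stride
  offsets): 14-bit raw counts plus white/dark frames, water absorption
  features near 1450/1050 nm, a structural-carbohydrate feature near
  1630–1690 nm, scattering soil background, and injected dead pixels.
- **`pipeline`** — configuration-driven strategy search
  (pre-treatment × reduction × segmentation grid) and whole-box runs.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance suite: analytic design
numbers, oracle equivalences (Bhattacharyya closed form, brute-force Otsu,
exhaustive k-means, dense ALS solve), closed-form invariants, registration
accuracy, and seeded end-to-end parameter recovery.

## CLI

```sh
rhizospec simulate --preset ci --seed 1 --out scene/      # synthetic scene
rhizospec normalize scene/stride_00.raw --white scene/white.raw \
    --dark scene/dark.raw --out norm_00.raw
rhizospec segment norm_00.raw --algo threshold --out mask.png
rhizospec stitch mask_*.png --overlap 0.1 --out box.png
rhizospec measure box.png --out lengths.csv
rhizospec radial norm_00.raw --mask mask.png --out allocation.csv
rhizospec decay --series series.json --mask mask.png --out decay.json
```

Axis convention: `data[row, col, band]`, row = along-scan (y), col =
across-track (x), 0-based everywhere; ENVI `lines` = rows, `samples` = cols.

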