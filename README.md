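# mammodensity

Fully automated measurement of mammographic percent density (PD) from
digitized film mammograms, and penalized-regression risk scores that capture
image information beyond PD.

Mammographic density — the fraction of radiologically dense fibroglandular
tissue on a mammogram — is one of the strongest breast-cancer risk factors,
but the reference way to measure it (an expert reader interactively choosing
two gray-level thresholds per film) takes minutes per image and depends on
the reader.  This package reproduces that read automatically: it extracts the
breast region, measures the image under a suite of fifteen classical global
thresholding algorithms, and trains a model that mimics a reference PD read,
so that archives of film mammograms can be scored in seconds per image with
no reader in the loop.

## Method in brief

For each image the pipeline computes a fixed-layout vector of ~1,100
measurements: for every thresholding method *m* (IsoData, Huang, Intermodes,
Li, MaxEntropy, Mean, MinError, Minimum, Moments, Otsu, Percentile,
RenyiEntropy, Shanbhag, Triangle, Yen), object statistics of the dense-tissue
mask on the preprocessed image and on a background-subtracted, watershed-split
version, plus whole-breast, edge-filter and thinning-pass statistics
(area, perimeter, circularity 4πA/P², solidity, gray-level moments, fitted
ellipses).  The matrix is reduced by PCA to the components capturing 90% of
training variance, and a lasso regression of √PD on the components

    minimize  ½ Σᵢ (√PDᵢ − β₀ − xᵢᵀβ)²  +  λ ‖β‖₁

with λ chosen by repeated tenfold likelihood cross-validation gives the
automated PD measure ("mimic PD" = clipped square of the linear predictor).
Three penalized logistic models of case-control status — PCs only; PD forced
in unpenalized + PCs; PD penalized + PCs — yield scores 1–3, each the sum of
its nonzero PC coefficients times the image's PC values.  An evaluation
battery (Pearson r with Fisher-z CI, Bland–Altman limits of agreement,
categorical odds ratios, ROC AUC with the DeLong test, deviance/LRT/AIC
tables) quantifies agreement with the reference read and discrimination of
case status.

A seeded phantom generator renders breast-shaped images with exact
ground-truth density, so the whole pipeline is testable end to end without
patient data.

## Worked example

```bash
mammodensity simulate --out cohort/ --n-cases 50 --n-controls 50 --seed 5
mammodensity extract  --images cohort/ --out features.csv
mammodensity partition --labels cohort/labels.csv --out split.csv --seed 5
mammodensity train --features features.csv --reference-pd cohort/truth.csv \
    --labels cohort/labels.csv --split split.csv --out bundle.json \
    --repeats 8 --seed 5
mammodensity evaluate --bundle bundle.json --features features.csv \
    --reference-pd cohort/truth.csv --labels cohort/labels.csv \
    --split split.csv --out report.json
```

The same flow in Python, on a small phantom set:

```python
import numpy as np
from mammodensity import PhantomSpec, generate_phantom, background_mask
from mammodensity import build_histogram, auto_threshold, apply_threshold

image, truth = generate_phantom(PhantomSpec(target_pd=30.0, seed=7))
mask = background_mask(image)
hist = build_histogram(image, mask)
level = auto_threshold(hist, "Otsu")
dense, fraction = apply_threshold(image, mask, level)
print(f"true PD {truth.pd:.1f}%  Otsu estimate {100 * fraction:.1f}%")
```

prints

```
true PD 30.0%  Otsu estimate 29.2%
```

— the Otsu threshold recovers the phantom's known 30% density to within a
percent, before any model fitting.  After training, `report.json` contains
the agreement and discrimination statistics; on a 200+200 phantom cohort the
held-out mimic-PD-versus-truth correlation is ≈0.98 and the mimic's
case-control AUC sits above chance at the simulated density shift (the exact
values for a given seed are reproduced by the acceptance script below).

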