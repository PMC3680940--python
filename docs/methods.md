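# Methods

`mammodensity` measures mammographic percent density (PD) from digitized film
mammograms without a human reader, and builds risk scores that carry image
information beyond PD.  This note records the models, the parameters that
matter, the numerical choices, and what the synthetic phantoms do and do not
establish.

## Pipeline

1. **Tag removal** (`io.crop_tag`).  Film mammograms carry a bright
   patient-identification tag.  Auto mode thresholds the whole frame with the
   Kittler–Illingworth minimum-error criterion, labels bright 8-connected
   components, and blanks any component that touches a frame corner, occupies
   less than 5% of the frame, and lies above the threshold.  "Blanking" sets
   the pixels to the film-background level rather than cropping rows/columns,
   so the image stays aligned with any externally supplied masks.  An explicit
   rectangle can be given instead; a rectangle covering more than half the
   frame is rejected.

2. **Breast segmentation** (`io.background_mask`).  A grayscale erosion (disk
   footprint) followed by a Gaussian blur suppresses texture and film grain;
   the minimum-error threshold on the 256-bin histogram of the working image
   separates breast from background; the largest connected component, holes
   filled, is the breast mask.  Defaults scale with image height: erosion
   radius 5 px and blur sigma 4 px at 1000-px height.  Near-constant frames
   raise a degenerate-input error rather than returning an arbitrary mask.

3. **Thresholding suite** (`thresholds`).  Fifteen classical global
   algorithms (IsoData, Huang, Intermodes, Li, MaxEntropy, Mean, MinError,
   Minimum, Moments, Otsu, Percentile, RenyiEntropy, Shanbhag, Triangle, Yen)
   implemented from their published objectives on 256-bin histograms.  Deeper
   images are linearly rescaled into 256 bins first.  Conventions, stated
   because downstream numbers depend on them bit-exactly: a pixel is *dense*
   iff its level is strictly above the returned threshold; ties between
   equally good split points go to the lower level; all methods operate on
   the normalized histogram, so they are invariant to scaling the counts.
   Li is solved by exhaustive minimisation of the cross-entropy criterion
   (the classical fixed-point iteration can stall in a local optimum and has
   no deterministic tie rule).  The minimum-error criterion floors class
   variances at 1/12 — the variance of the quantisation error — so the
   criterion stays defined when a class collapses onto a single level.
   Intermodes/Minimum smooth the histogram with an iterated 3-bin mean until
   exactly two maxima remain, and fail (explicitly) if 10,000 iterations do
   not reach bimodality.

4. **Feature extraction** (`segment`, `features`).  Per image, two passes per
   thresholding method: variant A thresholds the preprocessed image and
   measures objects of 5+ px as a single size class; variant B first removes
   background with a rolling ball (radius 50 px; estimated on a 4x-downscaled
   frame for radii above 16, the standard shrink trick), de-noises (3x3
   median by default), thresholds, splits touching objects with a
   distance-transform watershed, and summarizes three size classes (1–100,
   101–1,000, 1,001+ px).  Whole-breast statistics, a Sobel edge pass and a
   topology-preserving thinning pass (centerlines of the Moments-threshold
   dense mask, by default) complete the vector.  Per-object measurements
   follow the standard particle-analysis set: area, perimeter, circularity
   4*pi*A/P^2, solidity, mean/modal/median gray, integrated density, skewness
   and excess kurtosis of member intensities, and best-fit-ellipse axes and
   angle.  The perimeter uses the Crofton 4-direction estimator, which
   converges to the true boundary length for digitized convex shapes
   (chain-code perimeters overestimate circles by ~5% and would bias
   circularity to ~0.9); with it, a rasterized disc of radius 50+ px has
   circularity 1.00–1.01.  Kurtosis is reported as *excess* kurtosis; modal
   gray ties break toward the lowest level; objects under 5 px get NaN shape
   descriptors (shape is not meaningful at that scale and the 1–100 px class
   aggregates skip NaNs).  The slot order is owned by a versioned
   `FeatureLayout` registry (1,097 slots in version 1) whose SHA-256 hash is
   asserted in the tests; correctness is defined against the registry, not
   any particular count.  A failed pass yields NaNs, never an aborted vector.

5. **Feature matrix and PCA** (`matrix`).  Columns with `max_nan` (default
   200) or more NaNs are dropped, remaining NaNs become 0.  PCA is computed
   on the covariance of centered, *unscaled* features (the feature set mixes
   units; leaving the variables raw follows the original workflow — a
   `scale` flag standardizes first if wanted).  The retained count k is the
   smallest reaching 90% cumulative variance.  Sign convention: the
   largest-magnitude loading of each component is positive.  Test rows are
   always projected onto the training basis.

6. **Models** (`models`, `lasso`).  `DensityMimic` fits sqrt(PD) — the
   square-root transform makes PD approximately normal — on the PC scores
   with an l1 penalty; predictions square the non-negative part of the linear
   predictor and cap at 100.  `RiskScoreModel` fits penalized logistic
   regressions of case status: score 1 uses the PCs alone; score 2 forces PD
   into the model unpenalized (so the PC part is pushed toward independence
   from PD); score 3 penalizes PD together with the PCs.  A score value is
   the sum of nonzero PC coefficients times PC values — the PD coefficient is
   never part of the score.  Both classes return Results objects with
   `params`, `summary()`, `predict`/`score`.

## Lasso and lambda selection

The solver is coordinate descent on the objective `0.5 RSS + lambda * sum
|beta_j|` (gaussian) or `-loglik + lambda * sum |beta_j|` (binomial, IRLS
with a weighted-lasso inner solve and the working logit clipped at ±30 for
stability under quasi-separation).  Internally the columns are rescaled to
unit root-mean-square and the per-coordinate penalty absorbs the scale, which
leaves the objective identical while making the convergence tolerance
(max coefficient change per sweep, 1e-7 for final fits) scale-free.  An
active-set schedule (full sweep, iterate nonzeros, re-check) gives the usual
speedup on correlated designs.  Unpenalized covariates simply carry a zero
per-coordinate penalty.  KKT violations are checked in the tests.

Lambda comes from repeated k-fold likelihood cross-validation (default 10
folds; fold assignment is a seeded shuffle, stratified by case status for
binomial models).  Per repeat, the out-of-fold log-likelihood (profile
gaussian form `-n/2 log(RSS/n)`, or Bernoulli log-likelihood) is maximised
over lambda: a 12-point log-grid scan brackets the optimum — the CV curve is
not reliably unimodal — and golden-section search refines it; the returned
lambda is the arithmetic mean over repeats.  CV-phase fits use a relaxed
tolerance (1e-5, 500 sweeps); the final fit at the selected lambda uses the
strict one.  `rule="1se"` instead returns the largest lambda within one
standard error of the optimum: likelihood-maximum selection is
prediction-optimal but over-selects (it retains spurious covariates with
substantial probability), so support-recovery claims in the tests use the
1-SE rule while the default remains the likelihood maximum.

## Evaluation battery (`evaluate`)

Pearson r with Fisher-z CIs; Bland–Altman mean difference with ±1.96 SD
limits and the slope/intercept/r of difference on mean; odds ratios across PD
categories by unconditional logistic regression with Wald CIs (default breaks
0/5/10/25/100, i.e. a low <5% class and merged upper classes; the six-category
display breaks are available); ROC AUC by the Mann–Whitney statistic with the
1/2 tie convention and DeLong variance; the DeLong test for two correlated
AUCs; and a deviance table for a set of logistic models, with P1 the LRT
against the null, P2 the LRT against a declared nested PD-only reference, and
AIC = deviance + 2 * parameters.  The two-group cohort summary reports
mean (SD) with t tests, medians with Wilcoxon rank-sum, and count (percent,
one decimal) with chi-square.

## Synthetic phantoms (`phantom`)

A phantom is a half-elliptical "breast" attached to the left frame edge on a
dark film background (12-bit by default, tissue at 0.38 and film at 0.04 of
the intensity range), with dense tissue built by thresholding a smooth random
field — 12 Gaussian blobs (sigma ~9 px) plus a smoothed-noise texture — at
the exact top-k quantile reaching the requested PD, so ground truth is an
exact pixel count captured before noise.  Optional corner tag, multiplicative
vignetting (0.15), and additive Gaussian noise (sd 0.015 of range) emulate
digitization artifacts.  Cohorts draw per-subject PD on the sqrt scale from a
truncated normal (mean 3.4, sd 1.3 — medians near the 11–17% range typical of
postmenopausal screening populations), with cases shifted by a configurable
amount (default +0.8) on the sqrt scale, matching the scale on which the
density model works.

What the phantoms do *not* emulate: pectoral muscle, skin line and nipple
structure, scanner calibration drift, film artifacts other than one tag, and
realistic parenchymal texture.  Passing the phantom-based tests therefore
establishes internal correctness of the pipeline (masking, thresholding,
measurement, model fitting and evaluation close the loop on known truth), not
clinical performance on real mammograms.

## Problem sizes and runtimes

The test suite and the acceptance script run the full pipeline at desk scale:
a 100-phantom cohort (256x256) for parameter recovery (held-out Pearson r of
mimic PD against true PD) and a 200-case/200-control cohort with the 0.8
sqrt-PD shift for the risk-direction checks (AUC above chance, score-PD
correlation ordering).  Cross-validation uses 8 repeats of 10-fold CV in the acceptance
script and 4 in the test suite; the `CVConfig` default is 100 repeats for
production use.

## Known limitations

* The 15-method roster and the slot layout follow the classical
  particle-analysis toolchain; other implementations order or name the
  methods differently.  The layout registry is versioned for exactly this
  reason.
* Binomial fits under complete separation raise rather than returning an
  arbitrary solution; during CV such folds score -inf, which simply steers
  the search to larger lambda.
* Score 2 can legitimately end up with no nonzero PC coefficients — once PD
  is forced into the model, the PCs may carry no additional case-control
  information and the score is then identically zero.  On the phantoms,
  whose dense masks are the only case-control signal, this is the expected
  outcome; on real mammograms texture information can survive the penalty.
* The evaluation ORs are unadjusted (risk-profile style), matching the scope
  of the battery; covariate-adjusted models are out of scope.
* Only MLO-like single-view grayscale rasters are handled; DICOM and
  cranio-caudal views are out of scope.
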