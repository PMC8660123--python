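# Methods

## The classification problem

A myocardial-perfusion SPECT polar map condenses the three-dimensional
left-ventricular uptake distribution into a single 175×175 grayscale
image: a bright disc (the myocardium, apex at the centre) on a dark
background. A normal study shows near-homogeneous uptake across the disc;
perfusion defects appear as contiguous angular territories of reduced
intensity. The task is binary: normal (label 1) vs abnormal (label 0).

## Band-slicing features

The image is partitioned into 5 horizontal and 5 vertical bands and pixel
intensities are summed per band, yielding 10 attributes per map. For the
175-pixel default every band is exactly 35 pixels; for other sizes the
partition is near-equal with remainder pixels assigned to the last bands
(a fixed, documented rule — any consistent rule works, but it must be
deterministic). Bands are indexed h1..h5 top-to-bottom and v1..v5
left-to-right; row 0 is the top of the image.

Sums are computed in 64-bit integer arithmetic (the maximum possible band
sum, 35·175·255 ≈ 1.6·10⁶, is far from overflow, but the wide accumulator
makes the conservation identity Σh = Σv = total intensity exact rather
than approximate). This identity, and the exact permutation behaviour of
the band sums under right-angle rotation, are the two invariants the test
suite leans on hardest.

Multi-channel TIFF inputs are collapsed to one channel by the per-pixel
channel mean, with a warning; the intended inputs are single-channel.

## Synthetic phantoms

The generator emulates the statistical regime of a clinical polar-map
cohort, not its physics:

- a centred disc of radius 0.48 × image width (≤ 0.5 so rotation about the
  grid centre never clips it);
- per-map base intensity ~ N(180, 10) on the 8-bit scale, plus independent
  per-pixel noise with sd 8 — bright, mildly variable uptake;
- abnormal maps receive 1–3 angular-sector defects, each spanning 30–120°
  at full radial extent, multiplying in-sector intensity by (1 − severity)
  with severity uniform on [0.3, 0.9]. Sector geometry matches how
  perfusion defects present on bull's-eye maps (contiguous angular
  territories);
- cohort structure: 108 normal and 899 abnormal maps by default at the
  call site, organised into patients — male patients contribute
  stress/rest/prone maps, female patients stress/rest, with the per-class
  male patient fractions 10/49 (normal) and 91/404 (abnormal). Phase and
  sex never influence the pixels or the features; they exist so cohort
  summary tables can be reproduced.

The defect parameters (count, extent, severity and the intensity/noise
levels) are the package's definition of a "moderately severe" regime: a
90° sector at severity 0.6 removes ~15% of disc intensity, well above the
noise floor, so the classes are separable but not trivially so at the
small end of the ranges. Ground-truth defect parameters are recorded on
each synthetic map for oracle tests, invisible to the classifiers.

What the phantoms do **not** emulate: Poisson counting statistics,
attenuation and reconstruction artifacts, the clinical colour lookup
table, apex-to-base radial structure, or inter-patient anatomy. Passing
tests on phantoms therefore validate the *pipeline* — counts, leakage
freedom, feature algebra, calibration — not clinical accuracy; test-set
metrics on phantoms run higher than the same pipeline would achieve on
hospital data.

## Rotation augmentation

Normal maps (~10% of the cohort) are augmented with three rotated copies
each, which raises the normal fraction of a full training set from
108/1007 ≈ 10.7% to 432/1331 ≈ 32%. The default angles are 90°, 180°,
270°: on a square grid these are exact index permutations — lossless,
interpolation-free, and mass-conserving to the last count — making the
augmented rows reproducible bit-for-bit. Arbitrary ("small") angles are
supported via configuration with nearest or bilinear interpolation and a
constant fill; for a centred disc on a dark background the mass error of
a bilinear 10° rotation is well under 1%. Exact right angles are the
default because they are the only choice with no free parameters.

Augmentation operates on images and features are re-extracted afterwards:
rotation permutes and mixes band sums, so synthesising augmented rows in
feature space would be incorrect. Augmented maps keep their source's
label, phase, sex and patient id and are marked `provenance="augmented"`.

## Cross-validation and leakage control

Folds are stratified on the label with a fixed shuffling seed. At 10.7%
prevalence an unstratified 10-fold split has a realistic chance of a
nearly single-class test partition; stratification keeps each fold's
class mix within one image of the global mix. Folds are drawn over
images, not patients; an analysis grouping the 2–3 maps of one patient
into the same fold would be stricter and is left to future work.

Per fold: the training partition is every acquired map outside the fold;
its normal members are augmented; features are extracted from the union;
the model trains on that matrix and is scored on (a) the same training
matrix and (b) the features of the fold's acquired maps only. Because
augmentation happens strictly inside the training partition, no rotated
copy of a test map can reach its own fold's training set; the run asserts
this by object identity and records the verdict (`leakage_free`) in the
report. Training-block metrics are computed on the matrix the model was
actually fitted to, i.e. including augmented rows — that is the quantity
that saturates at 1.000 for memorising learners; metrics on unaugmented
training rows can be recomputed from the returned models if needed.

## Models

Four ensemble families under one contract: AdaBoost, gradient boosting
and random forest from scikit-learn, XGBoost from xgboost. Defaults are
each library's documented defaults (forests thereby train unrestricted
trees, `max_depth=None`), with `n_jobs=1` where applicable for
reproducible single-CPU runs; any hyperparameter can be overridden per
model and unknown keys are rejected when the model spec is constructed. The effective
parameter set is embedded in every trained model and report. Class
weighting is off: imbalance is handled by augmentation, not by weights.

Scores are `predict_proba` probabilities of the configured positive
class. The positive class defaults to **abnormal** (label 0): at ~89%
abnormal prevalence, precision and sensitivity are only informative for
the detection target, and the package's reported panels follow that
convention (configurable to `normal`).

## Metrics

Accuracy, precision = TP/(TP+FP), sensitivity = TP/(TP+FN), F1 =
2·P·S/(P+S), and AUC as the rank statistic — the probability that a
random positive outscores a random negative, ties counted half (midrank
convention, identical to the trapezoidal ROC area; computed via
scikit-learn and cross-checked in tests against a brute-force all-pairs
oracle). Hard labels use score ≥ threshold with the tie going to the
positive class; threshold defaults to 0.5.

Degenerate cases are explicit, never silent: a zero denominator yields
NaN plus a warning; AUC on a single-class partition is an error; NaN
values are excluded from aggregation. Across folds each metric is
reported as mean ± standard deviation, sample convention (n−1) by
default and configurable to population; a single-fold group reports sd 0
with a warning. Wall-clock fit time is recorded per fold for context but
is hardware-dependent and never asserted.

## Numerical and design notes

- All pixel data is 8-bit unsigned; feature arithmetic is int64; scores
  are float64 clipped to [0, 1].
- Determinism: phantom generation, fold shuffling and model fitting each
  take an explicit seed; identical (config, seeds) reproduce reports
  exactly. The acceptance script derives its three sub-seeds from one
  command-line seed via `numpy.random.SeedSequence`.
- Feature CSVs carry the fixed header `h1..h5,v1..v5,label`; schema
  violations are errors. Labels travel in a manifest CSV, never in
  filenames. YAML configs reject unknown keys.
- Cross-validating a precomputed feature CSV is supported only with
  augmentation disabled, since rotations cannot be applied in feature
  space.
- Problem sizes in the test suite and acceptance script: the study-scale
  runs use the full 1,007-map cohort with one forest; the four-family
  demonstration lives in `examples/04_cross_validation.py`; property
  suites use 100–1,000 small random grids. These sizes make the full
  suite complete in well under a minute while still exercising every
  stage at cohort scale.

## Known limitations

- Phantom realism as above; no claim of clinical performance transfers
  from synthetic runs.
- Folds are per image, not per patient, so the 2–3 maps of one patient
  may straddle train and test; the rotated-copy leakage that the pipeline
  guards against is a separate and fully controlled channel.
- The exact rotation angles and interpolation used in prior clinical
  applications of this augmentation are not standardised; the right-angle
  default is a reproducibility choice, not a claim of equivalence.
- Probability calibration, per-territory defect localisation, nested
  hyperparameter search and dimensionality reduction (PCA/ICA) are out of
  scope.
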