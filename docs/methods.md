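# Methods

## Scope and model

`wearact` implements an activity-of-daily-living classification analysis
for body-worn tri-axial accelerometers: windowed time-domain feature
extraction, Relief-F feature ranking, classifier evaluation under
subject-held-out cross-validation, and re-deployment of a trained model on
a cohort acquired with different hardware. Because the human datasets such
analyses are built on are rarely redistributable, the package ships a
first-class synthetic-cohort generator that reproduces the statistical
structure the analysis relies on; every quantitative claim the test suite
makes is therefore a statement about this synthetic family, not about any
particular human cohort.

## Synthetic cohorts (`siggen`)

A sample is modelled as

    acc(t) = R · (g_dir + osc(t) + b_subject + ε(t)),

with `g_dir` the activity's unit gravity direction in the reference device
frame, `osc` a walking oscillation, `b_subject` a constant per-subject
offset, `ε` iid Gaussian sensor noise per axis, and `R` the device's axis
frame. Units are g throughout; the frame convention puts the upward body
axis on sensor z, so quiet standing reads (0, 0, 1) g.

Defaults, chosen once as representative of waist- or ear-worn recordings:

| parameter | default | rationale |
| --- | --- | --- |
| activity durations | 15 s each, 7 activities | typical supervised protocol length |
| sampling rate | 15 Hz (reference device) | low-power wearable telemetry |
| posture gravity table | standing +z; sitting tilted 15° toward +x; supine +x; prone −x; lying left +y; lying right −y | sitting differs from standing by a modest trunk tilt; lying postures are quarter-turns |
| walking oscillation | 0.4 g at 2 Hz on z, half amplitude in quadrature on x | step frequency ≈ 2 Hz; vertical acceleration amplitude of normal gait at the waist is a few tenths of a g, mediolateral/anteroposterior smaller |
| noise_sd | 0.05 g | MEMS accelerometer noise plus small postural tremor |
| subject_offset_sd | 0.05 g | mounting and anatomy variation across wearers |

Randomness is keyed on `(seed, subject_index)`, so a subject is bit-identical
whether generated alone or within a cohort. Transitions between activities
are abrupt; no transition samples are labeled. The generator does **not**
emulate: biomechanically realistic gait waveforms, within-activity posture
drift or restlessness, heel-strike transients, gyroscope channels, or
mislabeled segments. Passing tests show the pipeline recovers structure
from data obeying the stated model — not that comparable accuracies would
be reached on real recordings, where class geometry is less clean.

## Harmonization (`harmonize`)

Order: resample → rotate → median filter → normalize.

- **Resampling** is linear interpolation at exact target-period sample
  times. 50 → 15 Hz is a non-integer (10/3) ratio, so plain decimation
  cannot land on 15 Hz; interpolation hits it exactly. Labels follow the
  nearest original sample (earlier sample on a tie). Only down-sampling is
  supported; an up-sampling request is an error.
- **Rotation** must be orthonormal to 1e-9 (`RᵀR = I`); axis-permutation
  presets are available via `rotation_from_axes`. Rotation and linear
  interpolation commute, so their order is immaterial; normalization must
  come last so the standing reference lives in the final frame.
- **Median filter** default kernel is 3 samples with edge replication —
  the shortest kernel that removes single-sample impulses without visibly
  distorting a 2 Hz component at 15 Hz.
- **Normalization** subtracts the per-axis median of the samples labeled
  `standing`, computed per subject (inter-subject and mounting variation
  is exactly what it removes). A recording without standing samples is an
  error naming the subject. The step is idempotent, since the median is
  shift-equivariant.

## Features (`features`)

Windows are 1 s wide, shifted 0.5 s. Both are rounded to whole samples at
the recording rate; at 15 Hz the shift rounds 7.5 → 8 samples. Windows are
laid independently within each contiguous same-label segment, restarting
at the segment's first sample: a 15 s segment at 15 Hz yields exactly
floor((225−15)/8)+1 = 27 windows and no window ever mixes labels.

Standard deviations use the population form (divide by N), matching the
printed feature definitions, and the correlation r_ab = σ_ab/(σ_a σ_b) is
defined as 0 whenever either axis has zero variance, keeping all 19
features finite on perfectly static windows.

## Relief-F (`relieff`)

The update is implemented exactly as stated in the module docstring: for
each considered instance R, one nearest same-class hit and one nearest
miss per other class, the miss term weighted by the raw empirical prior
P(C). Numeric diffs are |difference| scaled by the feature's min–max range
over the whole table (a constant feature contributes 0); neighbour search
uses Manhattan distance on the same range-scaled features, excludes R
itself, and breaks ties toward the lowest row index. By default every
instance is visited in order (n = all), making the result fully
deterministic; subsampling is available with a seed. The variant that
renormalizes miss weights by 1/(1 − P(class(R))) — so they sum to one —
is available as `normalized_priors=True`; it rescales each instance's miss
contribution uniformly and rarely changes rankings. Rankings sort weights
descending with ties broken by the smaller feature index.

A caution for users: duplicating every instance changes the weights (each
instance acquires a zero-distance hit, collapsing the hit term), and can
in principle reorder features. This is inherent to the
nearest-single-neighbour update, not an implementation artifact.

## Classifiers (`classify`)

- **Gaussian naive Bayes**: per-class, per-feature Gaussians; priors are
  class frequencies; posteriors evaluated in log space and normalized with
  logsumexp. Variances are floored at 1e-9 (g²) so a zero-variance feature
  cannot produce infinite likelihoods. Each class needs ≥ 2 training rows.
- **kNN (k = 1, 3)**: Euclidean distance on per-feature min–max scaling
  fitted on the training data only; majority vote.
- **Determinism**: all argmax ties (posteriors, votes) resolve to the
  earliest class in the activity schema order; kNN distance ties resolve
  to the lowest training-row index.
- Heavier algorithms (polynomial-kernel SVM, multilayer perceptron,
  decision tree) are not re-implemented; they enter through a plugin
  registry wrapping any sklearn-contract estimator
  (`register_sklearn_plugins` provides seeded reference adapters).

## Evaluation (`evaluate`)

Folds are assigned at the subject level: subjects are shuffled by seed and
split into near-equal test sets (12 subjects / 6 folds → 2 test subjects
per fold), so no wearer contributes windows to both sides of a fold —
including the kNN scaling, which is fitted per training fold. Accuracy is
macro-averaged (unweighted mean of per-class recalls, reported as %,
rounded to 2 decimals for display), insensitive to class imbalance among
test windows. A class absent from a fold's training subjects is skipped in
that fold's model with a recorded warning; its test windows count as
errors. The sweep evaluates every (algorithm, f) pair for f = 1…19;
`best_setting` breaks ties toward fewer features, then earlier algorithm.

## Transfer (`transfer`)

The target cohort is harmonized into the source representation (resample
to the source rate, rotate by the inverse device rotation, filter,
re-normalize per target subject using that subject's own standing median)
and the source model is applied unchanged. Evaluation restricts ground
truth to the activity schema common to both scenarios; model classes
outside it (e.g. prone when the target protocol omits it) remain in the
model and count as errors if predicted. Target windows labeled outside
the common schema are rejected rather than silently dropped.

## Known limitations and observed behaviour

- On default synthetic cohorts the Relief-F ranking is led by the
  upward-axis statistics in the order **F3 (mean z), F12 (min z), F9
  (max z)** — F12 edges out F9 by a small, seed-stable margin (~5% of the
  weight). The cause is Relief-F's range scaling: the walking oscillation
  extends the observed max-z range above sitting/standing, enlarging F9's
  diff denominator, while the min-z range stays bounded by the lying
  postures (walking min-z ≈ −0.4 g lies inside [−1, 0]). Field studies on
  real cohorts have reported the upward-axis mean *and maximum* as the top
  two — a divergence worth remembering when reasoning from this synthetic
  family to real data, where lying-posture variability compresses the
  feature ranges that penalize F9 here.
- Accuracies on the default noise level saturate near 100%: synthetic
  class geometry is cleaner than real recordings (no transitional windows,
  no restlessness, no label noise).
- Problem sizes used by the shipped analyses: 12-subject source cohorts at
  15 Hz (2268 windows), 48-subject 6-activity target cohorts at 50 Hz
  (7776 windows after harmonization), 10 replicate seeds for the transfer
  comparison; property tests use smaller cohorts (2–8 subjects, shortened
  activity durations) chosen to exercise the same code paths.
- The standing-median normalization corrects constant offsets only; slow
  drift, temperature effects and scale-factor errors are out of scope.
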