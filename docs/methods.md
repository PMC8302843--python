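# Methods

`emgface` implements a complete facial-expression-recognition pipeline for
10-channel facial surface EMG (sEMG), together with the synthetic data,
evaluation procedures and wearability metric needed to exercise it end to
end. This note records the models, the defaults and why, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## Signal model and electrode layout

A recording is a `10 × T` array of microvolt samples at 1000 Hz. The ten
working channels correspond, in fixed order CH1..CH10, to the facial
action units AU1, AU2, AU4, AU9, AU10, AU26, AU12, AU23, AU17 and AU15 of
the Facial Action Coding System (FACS); CH6, CH8 and CH10 sit at the
corners of the mouth and carry the strongest signal during happiness. Each
recording is labelled with one of seven expressions (contempt, surprise,
sadness, happiness, anger, disgust, fear), an intensity level 1–5 (FACS
letters A–E), a subject id and an acquisition batch id.

Recordings are segmented into frames of N = 200 samples with a hop of 50
samples. At 1000 Hz that yields 20 frames per second with 75% overlap —
the hop is the only choice consistent with both the 200-sample window and
a 20 Hz frame rate. A recording of T samples yields
`floor((T − 200)/50) + 1` frames, each inheriting the recording's label
(a recording holds a single posed expression; mixed streams are handled by
the evaluation module's smoother).

## Features and batch normalization

Each frame maps to 20 features: per-channel RMS
(`sqrt(mean(x^2))`, the average discharge level) and per-channel IEMG
(`sum |x|`, total rectified activity), ordered as the RMS block then the
IEMG block. Some conventions define IEMG with a 1/N factor; either choice
differs only by a constant per column, which the scaler below removes, so
the plain sum is used.

Features are normalized with a robust scaler,
`f' = (f − median) / IQR`, with median and IQR (Q3 − Q1,
linear-interpolation quantiles — the same convention as
`numpy.percentile` and scikit-learn's `RobustScaler`) fitted per feature
column. Two properties motivate this choice:

* **Outlier robustness.** Median and IQR have a 25% breakdown point, so
  occasional extreme frames (movement artifacts) barely move the fit;
  mean/SD scaling does not share this property.
* **Exact batch-gain invariance.** Between-session differences in
  electrode contact act, to first order, as per-channel multiplicative
  gains. RMS and IEMG are homogeneous of degree 1, so a gain `a` scales a
  batch's feature column, its median and its IQR all by `a`, and the
  scaled features are unchanged up to floating-point rounding (asserted
  to 1e−9 in the tests). This is the pipeline's defence against batch
  effects.

The default scope fits one scaler per batch; at inference on a new batch
the scaler is fitted on that batch's own frames, which needs no labels. A
global scope is available for comparison. Zero-IQR (constant) columns are
median-centred with divisor 1.0 rather than dividing by zero. Fitting
requires at least 4 rows per group so the quartiles are defined.

## The classifier

A small convolutional network maps a scaled 20-feature vector to class
probabilities, with k = 7 for expression or k = 5 for intensity:

    dense(20 → 64, ReLU) → reshape 8×8 → conv 4×4 ×16 filters, valid, ReLU (→ 5×5×16)
      → max-pool 4×4 stride 1 (→ 2×2×16) → flatten (64) → dense(→ k) → softmax

The dense front end re-embeds the feature vector as a spatial map so the
convolution can detect joint activation patterns across channels. The
4×4 kernel / 16 filters / stride-1 pooling combination is the unique
assignment that passes through a 5×5 intermediate map and flattens back
to 64 units; a 2×2-kernel variant (7×7 intermediate) remains available in
`NetworkConfig` for comparison. Dimension-chain consistency is asserted at
construction.

The network is implemented directly on numpy: im2col convolution (the
8×8 map is small enough that each layer is a single matmul per batch), an
explicit backward pass, and Adam (lr 1e−3, β = 0.9/0.999). Training uses
a seeded stratified split — 2/3 training, 1/3 validation, per class —
cross-entropy loss, minibatches of 32, up to 200 epochs with early
stopping on validation loss (patience 20, best weights restored). All
initialization, shuffling and splitting derive from one seed, so a
(data, seed) pair reproduces the trained model bit for bit. Prediction is
the argmax of the softmax row; exact ties resolve to the lowest class
index (numpy argmax order).

## Synthetic data generator

No public corpus of labelled 10-channel facial sEMG exists, so the
package ships a generator that reproduces the statistical structure the
pipeline consumes:

* **Carrier.** Zero-mean Gaussian noise band-limited to 20–450 Hz (4th
  order Butterworth applied forward–backward; 250 ms padding trimmed to
  discard edge transients), the standard surrogate for a surface EMG
  interference pattern. The carrier is rescaled to a target RMS
  amplitude exactly.
* **Expression coding.** A fixed 7×10 activation matrix assigns each
  expression a channel weight profile in [0, 1], written from the FACS
  reading of each expression on the recorded AUs (e.g. surprise on
  AU1/AU2/AU26, anger on AU4/AU23). Rows are pairwise distinct, every row
  exceeds 0.5 somewhere, and the happiness row peaks strictly on the
  mouth-corner channels.
* **Intensity.** Channel amplitude is `weight × 8 µV × level^1.5`: a
  monotone but deliberately nonlinear amplitude–intensity map, since
  measured facial sEMG grows with posed intensity in a positive but
  non-proportional way. The exponent is configurable.
* **Noise and batches.** Additive baseline instrumentation noise
  (default SD 2 µV, white) and per-batch multiplicative gains (default
  two batches at 1× and 2×) complete the model. Gains multiply the summed
  burst + baseline, so a batch differs from another by an exact factor —
  matching what the robust scaler provably removes. Additive offsets can
  be injected through a custom config for stress tests, but are not part
  of the default conditions.

Every recording derives from a `numpy.random.SeedSequence` tree, making
whole datasets pure functions of (config, profile, seed).

What the generator does **not** model: motor-unit action potential
shapes, inter-channel crosstalk, motion artifacts, electrode drift within
a session, or inter-subject anatomy. Consequently the synthetic
recognition experiments validate the pipeline's mechanics (features,
scaling, training, evaluation protocol) and its batch-gain claim; the
high synthetic accuracies (typically ≥ 0.95 held-out) say nothing about
accuracy on human recordings, where class overlap is far larger.

## Evaluation procedures

* **Exact and fuzzy accuracy.** Intensity is physically a continuum, so
  adjacent-level confusions are benign: fuzzy intensity accuracy counts
  `|pred − true| ≤ 1` as correct — equivalently the tridiagonal band of
  the 5×5 confusion matrix. Fuzzy ≥ exact always.
* **Channel ablation.** Accuracy per channel subset, retraining the
  network with the input layer resized to `2·|subset|` features (a
  subset's per-channel features equal those of an acquisition restricted
  to that subset, so column selection is exact).
* **Batch robustness.** Train on one batch, test on another, with and
  without the robust scaler on identical splits and seeds.
* **Baselines.** SVM (RBF), random forest, k-nearest-neighbours and
  linear discriminant analysis (scikit-learn, fixed documented defaults)
  scored on the identical stratified split as the network — a paired
  comparison.
* **Stream smoothing.** Continuous per-frame label streams are stabilised
  by an odd-window sliding majority vote (default 5 frames = 250 ms;
  ties keep the current label) followed by merging runs shorter than
  `min_run` (default 3 frames) into their longer neighbour (ties merge
  leftward, preserving causality). The result is idempotent, preserves
  length, and localises clean transitions within half a window.

## Landmark wearability metric

Electrode restriction of spontaneous expression is quantified from 38
facial landmark points (2-D pixel coordinates; the nasal tip is the base
point). The 37 distances from the other landmarks to the base point
summarise facial geometry; the mean relative error

    MRE = mean_i |l_after,i − l_before,i| / l_before,i

between the natural-state photo and the electrode-attached photo measures
restriction. Normalising by the *before* distance is the reading that
makes the metric scale-free (camera distance cancels) and monotone in
restriction. Closed forms used as oracles: identity gives 0; uniform
scaling by `s` about the base gives exactly `|s − 1|`; rigid motions of
either set leave it unchanged. For repeated photos both orders of
averaging (per-photo MRE then mean, or pooled per-landmark errors) are
exposed, since either is defensible.

## Problem sizes and numerical choices

The synthetic-recovery experiments use two batches with 30 recordings per
(expression × intensity × batch) cell — 2100 one-second recordings,
35 700 frames — averaged over three training seeds; the directional
robustness and ablation experiments use 4 recordings per cell (280
recordings), also over three seeds. These sizes give stable estimates
while keeping a full run on a single CPU in minutes.

Other numerical details: quantiles interpolate linearly; the softmax
subtracts the row maximum before exponentiation; cross-entropy clips
probabilities at 1e−12; EDF export quantizes to 16 bits between the
per-channel physical extrema (round-trip is therefore lossy at the
quantization step, unlike the delimited dialect, which round-trips
bit-exactly via `repr` floats); degenerate landmark geometry (a point on
the base point) and sub-window recordings raise dedicated errors rather
than propagating NaNs.

## Known limitations

* The generator's realism is validated only at the level the pipeline
  consumes (RMS/IEMG statistics), not at waveform level.
* Frames from one recording land in both training and validation splits
  (per-frame splitting); held-out numbers on synthetic data are therefore
  optimistic relative to a recording-level split. The cross-batch
  experiment, which tests on entirely unseen recordings, is the stricter
  protocol.
* Batch effects beyond multiplicative gain (additive offsets, spectral
  changes) are not removed by the robust scaler and not part of the
  default generator conditions.
* The intensity head is trained across all expressions jointly; per-
  expression intensity models may behave differently.
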