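# Methods

## Overview

`gaitpipe` implements an analytic chain for markerless, single-camera gait
analysis: a 2D pose estimator (e.g. MediaPipe in 2D mode) reduces a
smartphone walking video to a time series of 33 named body landmarks per
frame at 30 Hz; this package takes over from there. It segments gait cycles
from the ankle-to-ankle distance signal, extracts a 109-dimensional
geometric feature vector from the second cycle, and evaluates how well
simple classifiers recover sex and age group (< 65 vs ≥ 65 years) from
those features under a leakage-guarded, repeated, stratified
cross-validation with top-k feature selection. Because no pose dataset is
bundled, a synthetic kinematic walker generates labeled cohorts with the
statistical structure the analysis assumes, so the entire chain is testable
end to end.

## Gait-cycle segmentation

During walking, the Euclidean distance between the two ankle landmarks
oscillates: maximal at full stride split, dipping to a prominent local
minimum twice per stride when the feet pass each other. In noiseless
geometry those minima would be zeros; with estimation jitter they are
"extreme local minima" instead. A gait cycle is the interval spanned by
three consecutive minima. Cycles tile the minima sequence without overlap,
sharing endpoints: with minima m1 < m2 < … , cycle 1 is [m1, m3) and cycle
2 is [m3, m5), half-open in frames so consecutive cycles never double-count
a frame. Only the **second** cycle is analyzed, keeping clear of edge
artifacts at the start of the recording. The tiling interpretation (rather
than a sliding three-minima window) is a design choice: it is the only
reading under which "the second cycle" is unambiguous.

The detector: (1) centered moving-average smoothing, window 5 frames
(window shrinks at the edges; window 1 disables smoothing); (2) strict
interior local minima, plateaus resolved to their leftmost frame; (3) a
minimum is retained only if its topographic prominence is at least 0.1 of
the smoothed signal's range. Both knobs are configuration-exposed; the
defaults are this package's choices, as the detector's tuning is not
published.

Extraction *fails as a value*, not an exception, because the feasibility
metric (fraction of recordings with an extractable second cycle) counts
failures. Two failure modes exist:

* `insufficient_minima` — fewer than five prominent minima;
* `irregular_cadence` — the coefficient of variation (CV) of the
  inter-minima gaps exceeds 0.2.

The second gate exists because a failed pose detection (landmarks placed on
non-human scene content) still produces a noisy ankle-distance signal with
many spuriously prominent minima; counting minima alone would accept it.
Walking produces nearly periodic minima (measured CV ≈ 0.03 for clean
synthetic walks, still < 0.1 under heavy loose-clothing jitter), while
uniform-noise recordings measure CV ≈ 0.5; the 0.2 threshold sits in the
wide gap between those populations and rejects all 400/400 simulated
detection failures while accepting every simulated real walk we generated.

## Feature extraction

Per frame of the second cycle: 15 joint-pair distances, converted from
pixels to meters with a scene scale factor `meters_per_pixel =
reference_length_m / reference_length_px` obtained from an in-video
reference object of known length; and 12 interior joint angles in [0, π]
radians, computed as the arccos of the clamped cosine between the two rays
leaving the vertex — pure vector geometry, invariant to translation,
rotation and uniform scaling, and independent of the y-down image
convention. Each of the 27 per-frame series is summarized over the cycle by
mean, SD, skewness and kurtosis, and the cycle's frame count is appended as
a walking-speed surrogate (at fixed frame rate, frames per cycle is
inversely proportional to cadence):

    15·4 + 12·4 + 1 = 109 features.

**Reconstructed sets.** The upstream method's exact pair/angle tables are
not public. The defaults here cover torso width and height (shoulder and
hip breadth, shoulder–hip drops), limb segments (upper arm, forearm, thigh,
shank, left and right), the ankle-to-ankle span, and both feet; the angles
are the elbows, shoulders, hips, knees and ankles plus a trunk angle
(nose–midShoulder–midHip) and a neck angle (ear–nose–midShoulder) using
virtual midpoints computed on the fly. Both sets are replaceable through
configuration and validated (exactly 15 unordered distinct pairs; exactly
12 triplets with endpoints distinct from the vertex).

**Moment conventions.** Population (n-denominator) central moments:
skewness is the Fisher–Pearson g1 = m3/m2^{3/2}, kurtosis is excess
g2 = m4/m2² − 3. A zero-variance series reports (mean, 0, 0, 0) with a
degeneracy flag rather than NaN so downstream matrices stay dense. A
zero-length angle ray likewise yields a configurable sentinel (default 0).

## Evaluation framework

Binary outcomes: sex (female = 1) and age group (≥ 65 years = 1).
The evaluation is a repeated stratified 5-fold cross-validation, repeated
20 times with different random splits: 100 resampled train–test evaluations
per (model, feature-subset size). The feature-subset size k is prespecified
and swept over 1..50.

The leakage guard is the framework's defining constraint: z-scaling
statistics (population SD; zero-variance features map to 0 in train *and*
test), the elastic-net logistic regression used for feature ranking,
the ranking itself (features ordered by |coefficient|, ties broken
lexicographically by name for reproducibility), the top-k truncation, and
the classifier fit are all computed on the training fold only, then applied
to the held-out fold. Class imbalance is handled by balanced weights
n_total/(n_classes·n_c) everywhere a fit occurs.

Folds are drawn once per repetition and shared across all k and both
models, so performance-vs-k curves differ only through the feature count,
not through resampling noise. The ranking is k-independent (a full ordering
truncated to k), so it is computed once per (repetition, fold). All seeds
derive deterministically from a single base seed via `SeedSequence`; two
runs with the same configuration are byte-identical, including CSV float
formatting (`%.10g`).

Models: elastic-net logistic regression (l1_ratio 0.5, inverse penalty
C = 1.0 in z-scaled units, saga solver with pinned shuffle seed) and a
histogram-based gradient-boosting classifier (≤ 255 bins, learning rate
0.1, early stopping off). The learners are scikit-learn implementations;
the published hyperparameters are unavailable, so these values are
documented reconstructions, all configuration-exposed. Metrics: AUC-ROC by
the Mann–Whitney rank formulation with half credit for ties; accuracy,
per-class sensitivity, per-class F1 and the Matthews correlation
coefficient from the explicit confusion-matrix formulas at threshold 0.5
(MCC defined 0 when a marginal is empty). Test folds with a single truth
class would be discarded and counted (at the cohort sizes used they do not
occur). Curves aggregate mean and population SD over the (up to) 100
evaluations.

## Exploratory analyses

Five views over the sweep output: (1) performance-vs-k curves;
(2) metrics stratified by BMI ≥ 25 vs < 25, computed on out-of-fold
predictions pooled across repetitions (per-fold strata would often be
single-class; single-class strata report threshold metrics with AUC marked
undefined); (3) complete pipeline re-runs per site subgroup — refit from
scratch on the subset, never a filtering of pooled results; (4) best/worst
individuals, operationalized as the mean out-of-fold probability assigned
to the individual's true class (the source analysis gives no formula; this
is threshold-free and repetition-averaged); (5) per-feature selection
frequency at fixed k, and per-class feature distributions with a
standardized mean difference (difference of class means over pooled
within-class SD) as the numeric counterpart of distribution plots.

## Synthetic cohort generator

The generator emulates the study protocol: side-view recordings at 30 Hz,
~4 strides per recording, cohort fractions 64.8% female and 37.9% aged
≥ 65 (matched exactly via largest-remainder rounding), a Thailand/India
site mix with site-specific camera scale (reference objects of ~240 and
~300 px/m), and a configurable rate of undetected pose failures.

The walker is a stylized sagittal-plane kinematic chain, not a validated
biomechanical model: the pelvis advances at `step_length · 2 · cadence`;
thigh angles follow `±A·sin(2π·cadence·t)` in anti-phase between legs with
`A = arcsin(step/2·leg)`; both knees share a flexion term at twice the
stride frequency that vanishes at the foot crossings — this keeps the
ankle-distance minima exactly evenly spaced at half-stride intervals, the
timing contract the segmenter is tested against; both leg chains hang from
the pelvis center (the hip landmarks keep their half-width offsets as a
stylized projection of pelvis breadth); arms swing in anti-phase with the
ipsilateral leg with constant elbow flexion; the torso is rigid and bobs at
twice the stride frequency; face and hand landmarks ride as rigid offsets.
Subject parameters are log-normal around field-plausible medians (stature
400 px ≈ 1.6 m at the protocol's camera distance, cadence 0.92 strides/s,
step length 0.39 stature).

Group effects are multiplicative shifts applied after the base draw, so
`effect_scale = 0` is an exact null world (seed-matched draws coincide
across groups). Defaults: males ×1.07 stature, ×1.08 shoulder width, ×0.95
hip width, ×1.15 arm swing; over-65 ×0.93 cadence, ×0.94 step length,
+0.02 phase-jitter SD. The study reports no quantitative effect sizes, so
these were calibrated once so the emulated cohorts land in the reported
performance regime — sex AUC near 0.9, age AUC near 0.7, sex above age at
every k — and then frozen.

Noise: i.i.d. Gaussian landmark jitter, default SD 2 px (0.5% of stature;
the pose estimator's real jitter magnitude is unpublished — this is a
calibration choice, not a claim about MediaPipe); a loose-clothing mode
that triples jitter on hips, knees and ankles; random-walk phase jitter;
and whole-recording detection failures rendered as uniform-random
landmarks, deliberately unflagged so the segmenter must catch them.

**What the generator does not emulate — and what passing tests therefore
do not show.** No perspective or depth, no double-support asymmetries, no
turn-arounds, no occlusion by scene objects (an occlusion mode exists but
is off by default), no correlation between clothing and demographic
group. One measured consequence: heavy loose-clothing jitter *biases*
pairwise distances upward (Jensen effect on noisy endpoints) rather than
merely blurring them, so if degradation is confined to one class the
models learn the corruption as a class shortcut and the degraded
individuals are predicted *more* confidently — the opposite of the
qualitative field observation that loosely clothed individuals are
predicted poorly. The degradation test therefore corrupts a class-balanced
set of recordings and checks the effect on the age outcome, where the
corruption carries no label information. Synthetic results validate the
pipeline's mechanics and calibration, not real-world effect sizes.

## Calibration and problem sizes

The null-world check asks whether the framework manufactures signal. In a
single finite cohort, chance feature–label correlations are shared by
training and test folds, so one cohort's cross-validated AUC deviates from
0.5 by a dataset-level random offset (±0.07 is typical at n = 120 with 109
features) even when population-level independence holds. The check
therefore averages over four independent null cohorts of 120 recordings, 5
repetitions each (20 repetitions total), over the k grid {1, 5, 15, 50},
and requires every (outcome, model) mean AUC to lie in [0.40, 0.60].
Measured values across base seeds: 0.46–0.53.

Effect recovery runs one cohort of 150 recordings at the study class
fractions over k ∈ {5, 15} with 20 repetitions and requires the sex AUC to
exceed the age AUC at k = 15 for both models. The reduced k grids (and the
analysis scripts' 9-point grid spanning 1..50) reflect that the performance
curves plateau after roughly 10–15 features; the dense 1..50 sweep remains
the default configuration of the full pipeline and its cardinality is
checked structurally.

## Known limitations

* All features come from a single gait cycle; no multi-cycle averaging.
* The distance pair/angle triplet sets and model hyperparameters are
  reconstructions, not the published tables.
* The walking-speed surrogate is a frame count, not m/s.
* The generator's effect sizes are calibrated, so synthetic AUCs mirror
  the reported regime by construction; only orderings, calibration bands
  and mechanical properties (leakage, determinism, counts) are evidence.
* Visibility scores are carried through but unused by default (no
  published threshold); an optional filter exists in configuration.
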