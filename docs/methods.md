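# Methods

## Problem and model

The pipeline classifies a walker's affective state from marker-free
skeleton time series: per-frame 3-D positions of 25 Kinect-v2 joints at
30 Hz, recorded while the walker repeatedly traverses a ~6 m footpath
toward and away from a fixed camera. The working assumption is that
emotion modulates the *periodic* structure of gait — cadence, limb-swing
amplitude and phase — and that this structure is captured by the
dominant Fourier component of each motion channel within a straight
walking bout. The pipeline makes no biomechanical claims: it treats the
42 selected coordinate channels (14 joints × 3 axes) as generic periodic
signals.

## Preprocessing

**Joint selection.** The 14-joint subset (SpineBase, Neck, shoulders,
elbows, wrists, hips, knees, ankles) keeps the trunk and limb markers
that carry gait periodicity and drops hands, feet, head and mid-spine,
which either duplicate a neighbor's motion or are noisy in depth-camera
tracking. The order of the 42 columns is a fixed documented constant
(`MOTION_COLUMNS_42`).

**Body frame.** Subtracting the per-frame SpineBase position removes
the footpath translation and makes the representation invariant to
rigid translation of the whole scene (verified by a property test).
The SpineBase's own columns become identically zero; they are *kept* so
the printed dimensionalities (42 per frame, 84 per orientation, 168 per
record) stay intact, and their features are (0, 0) by the degenerate
convention below. The untouched camera-frame SpineBase track is carried
alongside, because segmentation needs the walker's absolute depth.

**Smoothing.** Each column is convolved with c = [1, 4, 6, 4, 1]/16, a
standard binomial approximation to a Gaussian low-pass. Edges are
mirrored (2 frames, no edge duplication) so the output length equals the
input length; shortening records near the 40-frame segment floor would
otherwise silently discard borderline segments.

**Differencing.** First differences emphasize the dynamic component and
remove slow drifts; the differenced matrix has T−1 rows, row *t* being
the change between original frames *t* and *t*+1.

**Segmentation and turn detection.** The per-frame depth change Δz of
the camera-frame SpineBase track is smoothed with the same 5-tap kernel
and each differenced row classified by sign: negative = approaching the
camera (*front*), positive = receding (*back*), |Δz| < ε = 2 mm/frame =
turning or standing (dead band). Additionally, 15 frames (~0.5 s) are
trimmed on each side of every sign change, because depth-camera joint
estimates degrade while the walker rotates. Remaining constant-sign
runs shorter than 40 frames (~1.3 s, less than one stride at normal
cadence) are discarded. The ε, trim and floor are exposed in
`PipelineConfig`. The dead band doubles as the turn detector in noisy
data: inflated sensor noise during a turn produces rapid sign flips
whose surrounding trims blanket the whole turn window.

## Feature extraction

For an N-sample channel the *main frequency* is k*·f_s/N where k*
maximizes |X_k| over k = 1…⌊N/2⌋ (DC excluded — after differencing the
mean is ≈ 0 anyway, and the stride fundamental is the physically
meaningful peak); the *phase* is arg X_{k*} ∈ (−π, π]. Ties break
toward the lowest bin; an exactly constant channel returns (0, 0). No
windowing or zero padding is applied by default (a Hann window is
available via config): segments are long relative to the stride period,
and the one-bin quantization this costs (f_s/N ≈ 0.2 Hz at N ≈ 150) is
the resolution limit acknowledged in the acceptance checks.

Per-record aggregation averages segment features within each
orientation arithmetically and concatenates [front freqs | front phases
| back freqs | back phases]. Arithmetic phase averaging is fragile near
the ±π wrap, so a circular mean (argument of the mean unit phasor) is
available as `phase_mean="circular"`; the arithmetic default preserves
the plainest reading of "averages". A record with zero front or zero
back segments cannot fill its 168 slots and is dropped with a logged
warning and a manifest entry — the alternative (imputing one
orientation from the other) would fabricate data.

## Normalization, PCA, classification

Features are z-scored column-wise (population SD; zero-variance columns
map to 0). PCA retains the minimal leading components whose cumulative
explained variance reaches the threshold (default 0.95; at threshold
1.0 all components are kept). Components come from a full SVD and are
checked in tests against a covariance eigendecomposition oracle.

Classifiers are deliberately wrapped, not reimplemented — the
contribution is the pipeline: Gaussian naive Bayes, random forest
(100 trees), RBF SVM (C = 1, γ = 1/d) and linear SVM (C = 1), under
stratified 10-fold cross-validation seeded for exact reproducibility.
By default normalization and PCA are fitted on each training fold only,
so no statistic of held-out records leaks into the model; `global_fit`
fits them once on the whole table for comparison with workflows that
normalize before splitting. Accuracy is pooled (total correct / total),
not the mean of fold accuracies, matching the "proportion correct"
definition; both are reported. Records from different cameras are never
mixed in one task unless `merge_cameras` is set, since the two sensors
observe different views and are processed independently.

## Synthetic gait generator

`synthgait` emulates the study conditions the pipeline targets: a
59-subject two-condition cohort, 1-minute records at 30 Hz, a 6 m
footpath with turns at each end. The SpineBase translates at 1.2 m/s
(a ~5 s pass ≈ 150 frames), pausing `turn_duration` = 1.5 s at each end
with joint noise inflated ×10; every other modeled joint is SpineBase +
rest offset + A₁ sin(2πf t + φ) + A₂ sin(4πf t + φ + φ₂) + N(0, σ²),
with contralateral left/right joints π out of phase, harmonic ratio
A₂/A₁ = 0.3, σ = 3 mm (typical Kinect jitter), distal joints swinging
more than proximal ones (ankle 12 cm fore-aft, wrist 9 cm). The 11
non-modeled joints ride rigidly on their nearest modeled neighbor.
Emotion effects shift cadence (`delta_freq`) and scale arm/leg
amplitudes; between-subject variation draws each subject's baseline
stride frequency from N(1.0 Hz, 0.05 Hz) and jitters speed by 5 %, both
shared across that subject's records as in a within-subject design.

What the generator does *not* emulate: bone-length constancy, ground
contact, occlusion and tracking dropouts, asymmetric or pathological
gaits, and any empirically measured emotion–gait coupling (the effect
sizes are constructed, not observed). Passing tests therefore show that
the pipeline recovers the signal family it was designed for and is
leak-free and deterministic — not that the constructed effect sizes
match real emotional gait changes, nor that real-data accuracies are
reproduced.

## Problem sizes and numerical choices

Tests and the acceptance script use the full 59-subject, 118-record
cohort at 60 s per record for the power and type-I checks (a few
seconds of compute), 20–30 s records elsewhere. Tolerances: oracle
agreement at 1e-8 or tighter; frequency recovery within one FFT bin
(f_s/N); the null-cohort accuracy is checked against the two-sided 95 %
binomial chance band at n = 118, [0.41, 0.59]. Degenerate inputs are
errors, not silent defaults: records with < 5 frames cannot be
smoothed, < 2 not differenced, tables with < 2 rows not normalized.
All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; reruns of any command with identical
inputs, config and seed are byte-identical (floats are serialized with
`repr`, JSON with sorted keys).

## Known limitations

- Main-frequency resolution is bin-quantized; very short segments give
  coarse frequency estimates (0.75 Hz at the 40-frame floor).
- Arithmetic phase averaging can cancel phases that wrap around ±π;
  use the circular option when phases matter.
- Segmentation assumes motion along the camera's depth axis; oblique
  footpaths would need a projected track.
- Real accuracies on human data depend on dataset, CV seed and PCA
  dimensionality; this package reproduces the procedure, not any
  particular dataset's numbers.
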