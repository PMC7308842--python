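# Methods

## Signal model and preprocessing

A body-worn accelerometer measures the sum of a gravitational component,
which rotates slowly with device orientation, and a dynamic component from
body motion. The pipeline separates them with a first-order Butterworth
low-pass at 2 Hz: the filter output is the gravitational **DC** signal and
the residual `AC = raw − DC` is the dynamic signal. Two choices here are
deliberate:

* **Zero-phase filtering.** The filter is applied forward-backward
  (`filtfilt`). Windows are processed offline, and a causal first-order
  filter would introduce a frequency-dependent phase lag that misaligns the
  AC/DC pair against the raw channel within a window. Forward-backward
  application squares the magnitude response (the effective amplitude gain
  at frequency f is |H(f)|²) and cancels the phase.
* **AC by subtraction.** Defining AC as the residual rather than as an
  independently designed high-pass guarantees exact reconstruction
  (`max |raw − (AC + DC)| < 1e-9` is asserted in the tests), so no energy is
  silently created or lost by the decomposition.

One caveat worth knowing: the digital filter is designed by bilinear
transform, whose frequency axis is warped relative to the analog prototype.
At 51.2 Hz sampling, a 10 Hz tone (39% of Nyquist) sees an amplitude gain of
0.0298 through the zero-phase filter versus 0.0385 for the ideal analog
|H(f)|² — the same attenuation to within one percentage point, but ~23%
apart in relative terms. Tests therefore compare measured attenuation to the
analog response on an absolute scale.

Raw, AC and DC are kept as **three separate signals** per axis. Orientation
and motion carry independent information (e.g. the periodicity of posture
changes vs. of limb movement), and feeding all three to the feature
extractor is one of the two ingredients (with the hierarchy) that makes this
compact pipeline competitive.

Decimation is literal stride sampling (`out[i] = in[i*stride]`, no
anti-alias filter), matching the reference processing of the 204.8 Hz
DaLiAc recordings down to 51.2 Hz; an optional anti-alias flag exists but
defaults off. Each channel is then z-scored over the whole recording
(per subject × device), *before* windowing — so between-activity amplitude
differences survive inside the windows while device- and subject-level
scale offsets are removed. Normalization is strictly per recording, which
also makes leave-one-subject-out evaluation leakage-free by construction
(no statistic of a held-out subject touches training data; the test suite
asserts this by corrupting one subject and checking all other feature rows
are bit-identical).

Windows are 5 s with 50% overlap: N = 256 samples at 51.2 Hz, starts at
multiples of 128. A window's label is the majority of its per-sample labels,
ties resolved toward the earliest-occurring label; mixed-label windows can
be dropped via `PipelineConfig(drop_mixed_windows=True)` (activities in the
target datasets are block-structured, so this rarely matters).

## Features

25 statistics per windowed channel; with 12 channels per device (3 raw acc,
3 AC, 3 DC, 3 gyro) that is 300 features per device and 1200 for four
devices. Time domain (20): mean; population standard deviation; population
skewness and *non-excess* kurtosis (a Gaussian scores 3; degenerate
zero-variance windows score 0 by convention); percentiles
[0, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 95, 100] by linear interpolation
between order statistics; range; RMS = sqrt(mean(x²)); and the number of
strict sign changes of the mean-subtracted signal (exact zeros skipped, so a
constant window has zero crossings).

Frequency domain (5), computed on x̂(ξ) = |DFT(x − x̄)(ξ)| over the
one-sided bins ξ = 0..N/2 (bin 0 is ≈ 0 after mean subtraction and is
included; under the 0·log 0 = 0 convention it contributes nothing):

| feature | definition | units / range |
|---|---|---|
| energy | E = Σ x̂² | amplitude² |
| entropy | H = −Σ p log₂ p / log₂(N/2), p = x̂/Σx̂ | [0, log₂(N/2+1)/log₂(N/2)] |
| centroid | c = Σ ξ·p | bins, [0, N/2] |
| bandwidth | b = Σ \|ξ − c\|·p | bins, [0, N/2] |
| max frequency | argmax x̂, ties → lowest bin | bin index |

Bandwidth uses the **absolute** deviation |ξ − c|: the signed deviation
δ = ξ − c has Σ δ·p ≡ 0 identically, so the mean absolute deviation is the
minimal meaningful reading of a p-weighted spread around the centroid.
Spectral features are reported in bin-index units (a `bin_to_hz` helper
converts; at N = 256 and 51.2 Hz one bin is 0.2 Hz). An all-zero spectrum
(constant window) takes E = H = c = b = max-frequency = 0.

Feature columns are ordered deterministically by (device, channel kind
[raw acc, AC, DC, gyro, mag], axis, feature) and named
`device|channel|feature`; matrices export to CSV with a JSON sidecar
recording the schema and pipeline configuration. Magnetometer channels
(mHealth) are treated like gyroscope channels — raw only, since the
gravity decomposition is physically meaningful for acceleration alone.

## Hierarchical classification

The hierarchy is a partition of the activity labels into ordered, named
meta-classes, encoded as data (JSON/YAML-serializable) rather than code. The
default 13-activity partition has eight meta-classes, four of them
non-singleton: {stand, wash}, {vacuum, sweep}, {walk, stairs up, stairs
down}, {bike 50 W, bike 100 W}. The base learner is trained on meta-class
labels; each non-singleton meta-class gets a sub-learner trained on the rows
whose *true* meta-class matches (the standard hierarchical training scheme —
training on base-predicted rows would couple sub-learner quality to base
errors). At prediction time a singleton meta-class is terminal; otherwise
the sub-learner decides, so the final label provably belongs to the
predicted meta-class, and base-level accuracy upper-bounds overall accuracy.
An all-singleton hierarchy reduces exactly to flat multiclass
classification (asserted down to identical predictions in the tests).

Learners (scikit-learn): logistic regression with L2 regularization and
penalty coefficient C = 1 (the default everywhere); KNN with k = 5; gradient
boosting with 500 estimators considering 10 features per split; SVM at
library defaults. A per-task learner map supports mixed-best systems (e.g.
gradient boosting for the base task, logistic regression elsewhere).

Two numerical choices of this implementation:

* **Feature standardization.** The scale-sensitive learners (LR, KNN, SVM)
  are wrapped in a standardizer fitted on their own training rows. The
  feature columns span orders of magnitude (spectral energy vs. percentiles
  of z-scored signals), and unstandardized L2-regularized logistic
  regression both converges poorly and misranks the penalty across columns.
  Gradient boosting, being scale-invariant, is left unscaled.
* **LR iteration budget** is raised to `max_iter=1000`; the library default
  of 100 can stop short of convergence on wide (≥ 1000-column) matrices.

## Evaluation protocol

`loso_split` yields one fold per subject. Per fold the model is fitted on
the training subjects' windows and scored on the held-out subject; the
summary reports the mean and the *population* standard deviation of the
per-fold accuracies, the confusion matrix summed over folds, per-class
precision (column-normalized diagonal), recall (row-normalized) and f-score
(harmonic mean, β = 1) computed at full precision from the aggregated
matrix (round for display; zero denominators yield 0 with a warning), and
per-sub-task accuracies: the base task scores meta-class predictions, and
each non-singleton sub-task scores final predictions restricted to rows
whose true class belongs to that meta-class (the model's own routing; an
`oracle_routing` flag instead applies the true meta-class's sub-learner).

`combination_sweep` evaluates every non-empty subset of device locations
(15 for four locations), each with and without gyroscope channels, ordered
by subset size then lexicographically. Features are extracted once over all
channels and column-sliced per subset, which is sound because feature
extraction is per-channel.

## Synthetic benchmark

The generator emulates what the feature set discriminates, not biomechanics:

* postures: a constant 1 g gravity vector at a posture-specific tilt plus
  white sensor noise (σ = 0.02 g);
* locomotion: sums of harmonics of an activity-specific fundamental
  (walk 2.0 Hz, stairs up 1.5, stairs down 1.8, run 2.8, jump 2.2 Hz) with
  activity-specific amplitudes (0.4–1.6 g on the dominant axis);
* household activities: band-limited, amplitude-modulated noise bursts with
  overlapping bands for vacuum and sweep, so that sub-task is imperfect by
  design;
* cycling: the two intensities share a 1.2 Hz fundamental and tilt and
  differ only in amplitude (2:1), the hardest pair for shape-based features
  (the per-recording z-scoring keeps the amplitude contrast because it is
  computed over all activities of a recording);
* gyroscope: periodic angular-rate signals scaled per activity, noise-only
  for postures.

Inter-subject variability: multiplicative gain ~ U(0.8, 1.2), a random
gravity tilt of up to 8°, cadence jitter of ±3%, and random phases, plus
fixed device-location gains (distal sensors see larger amplitudes). All
randomness derives from one integer seed through numpy's PCG64 via
`SeedSequence` spawn keys — same seed, bit-identical dataset on any
platform.

The standard benchmark is 6 subjects × 4 devices × 13 activities × 30 s per
activity block (930 windows, 1200 features), sized so the full LOSO run
takes seconds on one CPU while every activity contributes ≥ 10 windows per
recording. On it, the default logistic-regression hierarchy reaches ≈ 0.99
mean LOSO accuracy with the residual errors inside the stand/wash and
vacuum/sweep groups, and a shuffled-label control scores ≈ 1/13. What
passing these tests shows is that the pipeline's machinery — decomposition,
features, hierarchy, protocol — is correct and discriminates the intended
signal structure; it does *not* show field performance on real recordings,
which contain transitions, idiosyncratic styles, sensor artifacts and
less-characteristic activities the generator deliberately omits (no drift,
no dropout, no free-living behaviour).

## Degenerate inputs and tie-breaks

Zero-variance channels z-score to zeros; constant windows get skewness =
kurtosis = 0 and an all-zero spectrum with the zero conventions above;
spectral argmax ties resolve to the lowest bin; window-label ties resolve to
the earliest-occurring label; series shorter than one window yield no
windows (not an error), while series too short to filter raise.

## Known limitations

* The bundled reference confusion matrix ships for metric arithmetic and
  comparison; reproducing the published real-data accuracies requires
  downloading DaLiAc/mHealth (README). Four of the published per-class
  metric values differ by 0.001 from exact arithmetic on the published
  matrix itself; this package reports the definitional values.
* The DaLiAc reader's default column mapping may need adjusting to a given
  mirror of the dataset; the layout object makes that a one-line change.
* No streaming/real-time operation, no resampling by interpolation, no
  sensor calibration or axis re-orientation, no class-imbalance weighting.
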