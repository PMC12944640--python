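# Methods

`reachdecode` reimplements, on synthetic data, a complete EEG analysis for
decoding the direction of delayed center-out reaching movements: cohort
simulation, preprocessing, event-related spectral perturbation (ERSP)
mapping, a compact depthwise-separable CNN decoder, and post hoc
explainability (DeepLIFT relevance and interval occlusion) with
permutation/FDR statistics.  This note documents the models, the defaults,
the numerical choices, and what the synthetic data can and cannot show.

## Task and epoch geometry

The simulated protocol is a delayed center-out reach to one of five
targets on a 40 cm semicircular arc, 45° apart, labelled left,
middle-left, middle, middle-right, right.  Each trial: 2–3 s rest
(uniform), cue onset (target LED), 2 s preparation, go signal, 2 s
forward movement, 2 s hold, backward go, 2 s backward movement.  EEG is
60-channel (10–10 layout, ground at AFz excluded), generated at 512 Hz.

Epochs are cut relative to the forward go signal at 0 s: forward epochs
span [−3, +2) s (1 s baseline, 2 s preparation, 2 s execution) and
backward-preparation epochs span [−2, 0) s before the backward go.  All
intervals are half-open with 0-based sample indexing.  After downsampling
to 128 Hz a forward epoch is 60 × 640 samples.

## Synthetic EEG model

Each channel is the sum of:

* **1/f background noise** — Gaussian noise with power ∝ f^(−1), scaled to
  a per-channel RMS of `noise_amp` (default 4 µV), independent across
  channels.
* **Alpha (10 Hz) and beta (20 Hz) rhythms** — one sinusoidal carrier per
  band, *coherent across channels*: a regional oscillatory generator seen
  through volume conduction arrives at the electrodes at near-zero lag, so
  channels share the carrier phase and differ only in amplitude
  (alpha posterior-weighted, beta central-weighted Gaussian topographies;
  base amplitudes 8 and 4 µV).  The carriers run continuously; because
  rest durations are randomized per trial, carrier phase at the cue/go
  events is effectively random and trial averages contain no phase-locked
  component.

Event-related dynamics are amplitude envelopes, piecewise-constant per
interval with 100 ms cosine ramps (ramps avoid spectral splatter at
interval edges):

| interval (s, re go)     | envelope                        | default gain |
|-------------------------|---------------------------------|--------------|
| [−2.0, −1.5) cue        | posterior ERS                   | 1.5          |
| [−1.5, 0.0) preparation | posterior/central ERD, direction-coded | 0.55  |
| [0.0, +2.0) execution   | central, left-lateralized ERD   | 0.50         |
| backward prep (2 s)     | same direction-coded ERD, no cue transient | 0.55 |

Gains act on rhythm amplitude; a gain g multiplies band power by g².

### Direction coding

Only the preparation ERD depends on the target.  With s(c) ∈
{−1, −.5, 0, .5, 1} the left-to-right azimuth score and lat(i) ∈ [−1, 1]
the signed left–right channel coordinate, the per-channel amplitude gain is

    gain(c, i) = 0.55^w(i) · clip(1 + d · w(i) · [ lat(i)·s(c)
                                  + 0.6·s(c) + 0.4·(|s(c)| − 0.5) ], 0.05, 2)

where w(i) is the posterior spatial profile and d = `direction_effect`
(default 0.6; 0 makes classes indistinguishable).  The three terms are a
hemispheric interaction (left targets deepen right-posterior ERD and vice
versa), a scalp-common azimuth gradient, and a weaker eccentricity
gradient separating lateral from intermediate targets.  The exact maps
are recorded per subject in `GroundTruth`; they are a modelling device
for recovery testing, not a physiological claim.  The execution ERD is
identical across classes, so the execution interval is deliberately
uninformative — the designed contrast for the occlusion analysis.

An earlier variant of the generator used independent carrier phases per
channel and a purely antisymmetric (hemispheric-only) code.  Both choices
make the class signal second-order only (it appears in band power but in
no linear projection of the data), which the CNN cannot recover from a
few dozen trials; they were replaced by the coherent-carrier,
mixed-gradient model above, which is also the physically more natural
reading of a volume-conducted regional source.

### What the generator does not emulate

Ocular/muscle artifacts, bad channels, line-noise transients,
non-sinusoidal rhythm waveforms, inter-channel noise correlations, evoked
(phase-locked) potentials, and any biophysical head model.  Passing
recovery tests therefore demonstrates that the analysis machinery
recovers what was injected under these idealized conditions, not that it
would perform identically on recorded EEG.

## Preprocessing

Linear detrend per channel, zero-phase 4th-order Butterworth band-pass
1–60 Hz, zero-phase notch at 50 Hz (Q = 30); epoching; baseline
correction by subtracting each trial/channel's mean over [−3, −2) s
(backward epochs use the corresponding forward trial's baselines, having
none of their own); common-average re-reference; decimation 512→128 Hz
behind a zero-phase order-8 Chebyshev-I anti-alias filter.  Zero-phase
filtering throughout keeps interval boundaries aligned for the relevance
analysis.  No trial rejection is performed, and artifact handling
(RANSAC, ICA, interpolation) is intentionally absent — the synthetic data
are artifact-free; `condition()` exposes a hook where those steps would
sit in a real-data pipeline.

## ERSP

Time-frequency power is |CWT|² with the complex Morlet wavelet
(normalized bandwidth 1.5, center frequency 1.0) on a 4–40 Hz grid in
1 Hz steps (covers alpha 8–13 Hz and beta 13–30 Hz with margin).
Signals are reflect-padded by one maximum wavelet half-length so no
samples are discarded; the outer ~0.25 s of an epoch remains the least
trustworthy.  Per target position, power is averaged over trials and
normalized as ERSP = (P − B)/B with B the mean baseline power per
(channel, frequency); ERSP is bounded below by −1 and a gain g appears as
g² − 1.  Band maps average over the band then over ten 0.5 s windows
spanning [−3, +2) s.

Between-position statistics: for each band, window and position pair, a
paired two-sided sign-flip permutation t-test across subjects per channel,
with Benjamini–Hochberg correction over the 60 channels of that family.
Subjects (not trials) are the exchangeable units, matching a
grand-average presentation.

## Decoder

The network is the EEGNet-family architecture: 8 temporal filters
(length 16, linear, "same" zero padding with the extra sample trailing),
batch norm; depthwise spatial filters spanning all 60 channels (depth
multiplier 2 → 16 maps), batch norm, ELU, average-pool 4, dropout 0.1;
separable temporal convolution (16 filters, length 8), batch norm, ELU,
average-pool 4, dropout 0.1; flatten (width 16·T/16); dense softmax.
Convolutions are bias-free; batch norm uses momentum 0.1 and eps 1e-5.
An optional max-norm constraint on depthwise/dense weights exists but is
off by default.  The implementation is pure NumPy with exact analytic
gradients (verified against central finite differences); a fixed seed
reproduces training bit-for-bit.

Problems: fine (5 classes), coarse (left/middle/right, intermediate
targets discarded), proximity (left+right vs middle-left+middle-right,
middle excluded to keep classes balanced).

Training: within-subject stratified k-fold cross-validation (default 5),
with a stratified 20% of each training fold held out for validation;
Adam (lr 1e−4, batch 64, up to 250 epochs by default) on categorical
cross-entropy; the checkpoint with the highest validation accuracy is
restored.  Accuracy ties — common when the validation set is small — are
broken in favour of the *latest* tying epoch, so an early lucky plateau
does not arrest learning; this matters at the reduced problem sizes used
in the test suite and is documented here as a deliberate choice.

Metrics are computed on held-out test folds only: row-normalized
confusion matrix, accuracy, macro-averaged F1, and macro one-vs-rest AUC.
Macro averaging is this package's definition choice for the multi-class
case.

## Explainability

**DeepLIFT** (Rescale rule, zero reference) is computed with respect to
the pre-softmax score of the trial's correct class — softmax saturation
makes post-softmax attributions degenerate.  Linear layers propagate
multipliers exactly; ELU uses the Rescale ratio (y − y_ref)/(x − x_ref)
with the analytic derivative substituted when |x − x_ref| < 1e−7.
Attributions are computed in float64 and satisfy summation-to-delta to
machine precision.  Subject maps: |attribution| averaged over a fold's
test trials, then over folds; the temporal view is the channel mean, the
spatial view a per-window time mean.  Deviation of temporal relevance
from its baseline level ([−3, −2) s mean) is tested per sample with the
sign-flip permutation t-test across subjects, BH-corrected over samples.

**Occlusion**: test trials are re-fed to trained models with all channels
zeroed in the preparation ([−2, 0) s) or execution ([0, +2) s) interval;
models are never retrained on occluded inputs.  Reported are
occluded-minus-intact confusion-matrix differences and accuracy deltas,
with per-cell paired t-tests across subjects, BH-corrected.

## Statistics

Sign-flip permutation t-tests enumerate all 2^n sign patterns when
2^n ≤ 2^14 (exact p) and otherwise use 10^4 Monte-Carlo flips with the
add-one estimator (b+1)/(n+1).  Zero-variance difference vectors yield
t = ±∞ (nonzero mean) or p = 1 (all-zero).  BH-FDR uses the standard
step-up procedure.  All tests are seeded.

## Problem sizes used in tests and the acceptance script

Full study scale (20 subjects × 300 trials, 250 training epochs) is the
package default but is far larger than needed to exercise the machinery.
The test suite and `scripts/acceptance.py` run reduced configurations,
chosen once as the package's own working scale:

* structural checks use the full defaults (they are cheap);
* decoding recovery uses a 3-subject positive-control cohort with a
  strong, low-noise effect (`direction_effect = 1.5`, `noise_amp = 0.5`,
  24 trials per target, 3 folds, 40 epochs at lr 1e−3, batch 8) and a
  matched null cohort (`direction_effect = 0`); at a few dozen training
  trials the paper-scale optimizer settings (lr 1e−4, batch 64) cannot
  converge, so the reduced scale raises the learning rate — the package
  default remains the full-scale setting;
* relevance/occlusion recovery reuses the positive-control models.

Chance levels are 0.2 / 0.33 / 0.5 for fine / coarse / proximity.  At
these reduced sizes the decoder's fold accuracies are variable; recovery
criteria are therefore formulated against fold means and standard errors
rather than single runs.

## Known limitations

* The synthetic effect calibration targets the qualitative regime of
  within-subject motor-preparation decoding, not any specific published
  accuracy value; real-data numbers are not reproducible from synthetic
  cohorts.
* The NumPy network trains on CPU only; full study-scale training
  (20 subjects × 3 problems × 5 folds × 250 epochs) is possible but slow.
* EDF export is not provided; the HDF5 container is the only persistence
  format.
* F1 is macro-averaged; other averaging conventions will give different
  values on imbalanced predictions.
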