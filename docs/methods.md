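# Methods

`shallowbp` implements a two-stage cuffless blood-pressure estimator for
synchronized PPG/ECG/ABP waveform segments (125 Hz, 1024 samples ≈ 8.192 s):
a signal-conditioning front end, a shallow 1-D U-Net autoencoder whose dense
bottleneck acts as a learned feature extractor, and per-target regressors
mapping features to systolic (SBP) and diastolic (DBP) pressure. This note
documents the model, its assumptions, the parameters that matter, the
synthetic-data generator, and the numerical choices made where the design
was genuinely open.

## Signal conditioning

**Baseline-drift correction.** Local maxima of the raw segment give a median
inter-peak spacing `d`; a moving minimum with window `d` approximates the
wandering baseline; a polynomial fitted to that curve is subtracted; the
result is shifted to minimum 0 and rescaled so its range equals the input
range exactly. The polynomial order is `min(round(d), order_cap)` with
`order_cap = 8` — an order of ~`d` (≈ 90 for typical beats) is numerically
meaningless, so the cap is a deliberate deviation; the fit uses a
centred/scaled abscissa. With fewer than two detected peaks the signal is
fitted directly with an order-6 polynomial (fallback branch). Constant
inputs are returned unchanged and flagged degenerate instead of dividing by
zero. For the pressure channel the corrected waveform is re-anchored to the
original minimum: pinning every ABP segment's minimum to 0 would destroy
the mmHg level that both the global normalization and the labels rely on,
so level preservation takes precedence over the literal min-0 contract for
that channel (labels are in any case extracted from the *raw* mmHg ABP,
before any correction).

**Normalization.** Predictor channels are z-scored then affinely mapped to
[0, 1] per segment (equivalently `(x − min)/range`; the two-stage form is
kept and the equivalence is asserted in tests). The pressure waveform is
divided by a single global systolic maximum so segments retain their
relative amplitude — the amplitude *is* the label information. To avoid
test-set leakage the divisor is a training-partition statistic, frozen into
a `NormalizationContext` and reused for held-out data; computing it over
everything (the strict variant) is available by passing no context.

**PPG derivatives.** Velocity (VPG) and acceleration (APG) channels are
first differences divided by the unit sample step, band-passed with a
linear-phase equiripple FIR (stop/pass/pass/stop 0.25/0.5/10/15 Hz at
125 Hz, 51 taps). The band edges pass cardiac fundamentals and derivative
harmonics while killing drift and differentiation noise; linear phase makes
the group delay exactly (taps−1)/2 = 25 samples, compensated by shifting
VPG by one delay and APG by two. The chain consumes `2·delay + 2` samples,
so segments are ingested with a 52-sample margin (default synthetic length
1076); sources that are exactly 1024 samples long can opt into reflection
padding.

**Labels.** Per-segment SBP/DBP are the means of systolic-peak and
diastolic-trough amplitudes (`peak-mean`, the default) or the raw extrema.
Beat peaks require a topographic prominence of at least 0.1 of the signal
range (suppresses dicrotic-notch double counting) *and* an amplitude above
the signal midline — noise excursions on the long, nearly flat diastolic
runoff otherwise reach the prominence floor and masquerade as beats. Peak
amplitude is read as a ±1-sample mean and trough amplitude as a ±4-sample
mean: the raw sample at a detected extremum is selection-biased under
noise (upward at peaks, downward on the flat diastolic foot), and the short
window removes most of that bias at negligible cost in the noise-free case.
MAP = DBP + (SBP − DBP)/3.

**Quality screening.** A segment is rejected if any of the following holds
(first failed rule is reported): SBP outside [80, 190] mmHg, DBP outside
[50, 120], pulse pressure outside [20, 120] (all inclusive); a blank
(zero-range) PPG or ABP channel; peak-height standard deviation above 0.15
(unit-range amplitude) or peak-interval standard deviation above 0.20 of
the median interval on either PPG or ABP; or a beat count outside [4, 25]
per segment (≈ 30–180 bpm). The std ceilings and count window are not
published anywhere and were fixed here by requiring clean/distorted
separation on the synthetic fixtures (see below); all are configurable.

## Autoencoder

The network maps stacked predictor channels (declared order PPG, VPG, APG,
ECG; any subset preserves that order) to the globally normalized pressure
waveform. Encoder level *i* applies two same-padded convolutions of width
`w·2^i` with rectified activations, then factor-2 max pooling. At the
bottom, the pooled map (length `L/2^depth`, channels `w·2^(depth−1)`) is
flattened through a dense layer of `F` units — the feature layer — and a
second dense layer projects back to the pooled-map shape before the bottom
convolution block (`w·2^(depth−1) → w·2^depth`) and the decoder resume.
Decoder levels upsample by transposed convolution (kernel 2, stride 2;
nearest-neighbour + convolution available), concatenate the skip, and apply
two convolutions; a final 1×1 convolution produces one linear output
channel. Linear output matters: targets lie in (0, 1] but are *not*
per-segment ranged, and a saturating output would distort the amplitude
that carries the BP information.

With depth 1, width 128, kernel 3, four channels and 1024 features the
bottleneck map is 512×128, the feature layer holds 512·128·1024 =
67,108,864 weights, and the convolutional backbone has exactly 559,873
parameters; `count_parameters` returns closed-form counts that match the
built network exactly for every architecture.

The back-projection dense layer is an acknowledged addition — only the
first dense layer is priced in the published figure — so parameter
reporting keeps the two separate. The two bottleneck activations are leaky
rectifiers (slope 0.1) rather than hard rectifiers: the bottleneck's inputs
are pooled rectified maps and hence all non-negative, which makes the
per-unit weight updates sign-coherent; with hard rectifiers the entire
feature layer was observed to die irrecoverably within about ten optimizer
steps. Feature extraction returns post-activation values (a switch selects
pre-activation).

**Training.** MSE loss, Adam (step 1e-3, standard moment decays), batch 64,
up to 100 epochs, early stopping on validation MAE with patience 15 and
best-weight restoration; the validation split is a seeded random 20% of the
training segments. The stopping rule is "halt when epochs since the best
validation MAE reach the patience", so patience 0 trains exactly one epoch.
The implementation is pure NumPy in float32 with every random draw routed
through one seeded generator, so training, features and reports are
bitwise reproducible across reruns on the same build.

## Regression stage

One model per target — SBP and DBP regressors never share state. Features
and targets are both standardized with training-set statistics inside the
fitted pipeline (the target transform is inverted at prediction). Target
standardization is not cosmetic at desk scale: with the stock
multi-layer-perceptron recipe (Adam solver, ReLU, inverse-scaling schedule,
alpha 1e-4, automatic batch size, 500 iterations, 100 hidden units) and a
few thousand training rows, raw mmHg targets leave the optimizer spending
nearly its whole update budget learning the ~130 mmHg offset. The MLP's
convergence tolerance is tightened to 1e-6 so the plateau heuristic does
not halt the standardized-target loss early. Seven further algorithms
(k-nearest neighbours, support-vector regression, stochastic gradient
descent, AdaBoost, gradient boosting, XGBoost, random forest) run behind
the same interface with library defaults, recorded in the fitted spec.

## Synthetic data

The generator produces ground-truth-labelled PPG/ECG/ABP triplets with
shared beat timing. It emulates the *statistical structure* the pipeline
depends on — not hemodynamics:

- SBP/DBP are drawn from truncated normals on [80, 190]/[50, 120] mmHg with
  pulse pressure confined to [20, 120]. The targets (SBP 132.609 ± 21.703,
  DBP 63.705 ± 9.978 mmHg, the reference corpus statistics) are treated as
  moments of the *accepted* distribution: parent parameters are inverted
  numerically, including a deterministic Monte-Carlo correction for the
  joint pulse-pressure rejection, because plain truncation at the target
  moments undershoots the SD by ~2.4 mmHg.
- The ABP beat is a systolic bump with a small dicrotic shoulder on an
  exponential-free baseline, rescaled per segment so the extrema hit the
  drawn DBP/SBP exactly at zero noise (the label-recovery oracle).
- The PPG beat is a two-lobe pulse lagging the ECG R-wave by a constant
  0.25 s pulse-transit offset. Its peak amplitude grows strictly with pulse
  pressure, and — because per-segment normalization erases amplitude — its
  *shape* carries the recoverable BP information: the reflected lobe's
  relative amplitude (augmentation) grows with mean pressure
  (0.32 + 0.006·(MAP − 87), clipped to [0.10, 0.45]) and its arrival phase
  advances with systolic pressure (0.40 − 0.002·(SBP − 132.6), clipped to
  [0.31, 0.48], ≈ 35 ms per SD of SBP at typical beat lengths). These
  couplings mimic the stiffness-driven morphology changes that make
  cuffless estimation possible; their magnitudes were set so that the
  generator fulfils its contract — BP-predictive features exist by
  construction and survive the pipeline's own normalization — while staying
  within physiologically plausible ranges.
- White noise defaults to 2% of the pulse amplitude (a clean clinical
  recording); sinusoidal sub-cardiac drift and four distortion modes are
  injectable. The height and rhythm corruptions are alternating rather than
  uniformly random — roughly half the beats damped to 60% amplitude
  (pulsus-alternans-like), or per-beat periods alternating between 0.65 and
  1.35 of nominal (bigeminy-like) — because uniform ±40% scaling lands the
  resulting peak statistics *on* the default screening ceilings rather than
  beyond them; fixtures should be unambiguous. Measured on 500 records at
  these settings the default screen separates distorted from clean records
  with ≈ 97% sensitivity and ≈ 99% specificity, which is what justifies the
  unpublished threshold defaults above.

What the generator does **not** model: real pulse-wave physiology
(reflection is a caricature, no respiratory modulation, no arrhythmia
beyond the rhythm corruption, no sensor-specific noise), subject identity
beyond an id label, and any PPG–BP relationship other than the two couplings
stated above. Passing the synthetic end-to-end check therefore shows that
the implementation's plumbing, learning dynamics and evaluation are sound —
it does not certify accuracy on clinical data, which requires the full
corpora and full-scale training.

## Problem sizes and reproducibility

Desk-scale validation uses a quick profile: width 32, 128 features, depth 1,
kernel 3, PPG-only input, at most 10 epochs, and the MLP regressor, on
2,000 synthetic records (75/25 subject-disjoint split). PPG-only is the
quick default because at this scale additional input channels were observed
to promote shortcut reconstruction within the short epoch budget; the
four-channel stack remains the full-profile default. Under this profile the
held-out SBP MAE lands roughly 45–50% below the predict-the-training-mean
baseline (seeds 0, 1, 2, 7), with Pearson r ≈ 0.8. `scripts/acceptance.py`
re-runs this profile end to end, along with the worked examples and
calibration checks, and writes all quantities to JSON.

Determinism: given one seed, the synthetic draw, the validation split, the
weight initialization, the batch order and every downstream artifact
(feature matrix, reports) are bitwise reproducible; the seeded MLP is
likewise deterministic.

## Known limitations

- Algorithm-level fidelity to the published pseudo-code is bounded by its
  internal inconsistencies (polynomial order ≈ beat spacing; min-0 output
  for the pressure channel; an unstated difference step); each deviation is
  a documented design decision here.
- The NumPy network trains on one CPU core; it is intended for
  correctness-first, desk-scale experiments, not full-corpus training.
- The quality screen is threshold-based and global; no adaptive or
  subject-specific screening, no motion-artifact correction.
- The 5-fold and transfer procedures assume stores fit in memory.
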