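# shallowbp

Cuffless blood-pressure estimation from photoplethysmogram (PPG) and
electrocardiogram (ECG) waveforms, for researchers working on continuous,
non-invasive BP monitoring. The package implements a two-stage method: a
shallow 1-D U-Net autoencoder learns to map conditioned predictor channels
to the arterial blood pressure (ABP) waveform and exposes an in-line dense
bottleneck as a feature extractor; per-target regressors then predict
systolic (SBP) and diastolic (DBP) pressure per 8.192-second segment.
Results are scored with the field's standard stack: MAE, British
Hypertension Society (BHS) grading, AAMI compliance, and Bland–Altman
limits of agreement.

## The method

Segments are synchronized 1024-sample snippets at 125 Hz. Conditioning
removes baseline wander (moving-minimum + polynomial fit, range-preserving),
derives velocity/acceleration PPG channels (first differences through a
linear-phase FIR band-pass with exact group-delay compensation), extracts
per-segment SBP/DBP/MAP labels from the mmHg pressure waveform, and rejects
bad segments (label windows 80–190 / 50–120 mmHg, pulse pressure 20–120;
blank channels; non-uniform peak heights/spacings; implausible beat
counts). Predictor channels are normalized to [0, 1] per segment,

    x_norm = range01((x − μ) / σ),

while the pressure target is divided by one global systolic maximum so
segments keep the relative amplitude that carries the BP level:

    abp_norm = abp / SBP_global_max.

The autoencoder is a U-Net of depth *d*, first-level width *w*, kernel *k*:
per level two convolutions + ReLU and factor-2 pooling; at the bottom the
pooled map is flattened through a dense layer of *F* units (the feature
layer) and projected back before the decoder resumes with transposed-
convolution upsampling and skip concatenation. The flagship layout
(d=1, w=128, k=3, 4 channels, F=1024) has a 512×128 bottleneck, a
512·128·1024 = 67,108,864-weight feature layer, and a 559,873-parameter
convolutional backbone (~0.55 M). Training: MSE loss, Adam, batch 64,
early stopping on validation MAE with best-weight restoration. Features
feed one regressor per target (default: a 100-hidden-unit MLP); training is
fully seeded and bitwise reproducible.

The network is implemented in NumPy (float32, manual backpropagation,
deterministic under seed) — `shallowbp.nn` is a small, self-contained layer
library, and `UNetFeatureExtractor` / `BloodPressureRegressor` are
scikit-learn estimators that compose with sklearn pipelines and model
selection.

## Worked example

No clinical data is required: the `synth` module generates labelled
PPG/ECG/ABP segments whose pressure extrema match the drawn SBP/DBP exactly
at zero noise and whose pulse morphology co-varies with BP the way real
stiffness-driven waveforms do.

```python
from shallowbp.synth import SyntheticConfig, generate
from shallowbp.pipeline import PipelineConfig, run_pipeline

store, truth = generate(SyntheticConfig(n_records=2000, seed=0))
cfg = PipelineConfig.quick(seed=0, channels=1, max_epochs=10)   # width 32, 128 features
out = run_pipeline(cfg, store)
```

Output of this exact run (one CPU, ~2.5 min):

```
kept 1974 of 2000 segments after screening
test segments: 498
SBP: MAE 9.51 mmHg (mean-baseline 18.422), ME 0.035, SD 12.366, BHS D (35.141/61.847/79.116%), r 0.83, LoA [-24.202, 24.272]
DBP: MAE 6.469 mmHg (mean-baseline 8.1), ME 0.248, SD 8.528, BHS C (47.992/81.124/92.771%), r 0.614, LoA [-16.467, 16.964]
```

Reading this: the quality screen removed 26 segments (1.3%); on the
held-out subject-disjoint quarter the learned features cut SBP error to
roughly half of what predicting the training-mean would give (9.51 vs
18.42 mmHg, Pearson r = 0.83) after only 10 epochs of a width-32 model —
the feature pathway carries BP information. The BHS/AAMI grades are those
of a deliberately tiny training run on synthetic data; clinical-grade
numbers require the full corpora and the full-size model.

The same stages are available from the shell:

```bash
shallowbp simulate --n-records 2000 --seed 0 --out store.h5
shallowbp run store.h5 --workdir work --quick --channels 1 --seed 0
shallowbp sweep store.h5 --quick --axis depth=1,2 --seed 0
```

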