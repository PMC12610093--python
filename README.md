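# stcca — spatial-temporal coupled cross-attention for EEG speech decoding

`stcca` is a NumPy implementation of a hierarchical attention network for
decoding speech-related mental states (inner/imagined speech and similar
paradigms) from multichannel EEG trials, together with everything needed
to run it as a reproducible experiment: signal preprocessing, a
class-conditioned synthetic EEG generator, stratified and
leave-one-subject-out cross-validation, ablation machinery, robustness
probes and significance testing.

## The model

A trial is a matrix `x ∈ R^{ch×t}` (electrodes × samples) with a class
label `y ∈ {1..m}`. The network processes it in three stages:

1. **Local feature extraction (LFEM).** Two convolutional pathways:
   the temporal-first pathway applies a `(1, ⌊fs/10⌋)` kernel along time
   and then a `(⌊ch/2⌋, 1)` kernel across electrodes; the spatial-first
   pathway applies the same kernels in the opposite order. Each pathway
   is Conv→Conv→BatchNorm→ELU→AvgPool(4,4), and its output is flattened
   and area-resampled to a fixed sequence of 512 positions × k features,
   giving the temporal stream `f_t` and the spatial stream `f_s`.
2. **Coupled cross-attention fusion (CCA).** Scaled dot-product
   attention `Atten(Q,K,V) = softmax(QKᵀ/√d_k)·V` is applied in both
   directions between the streams — `f_ts = Atten(f_t, f_s, f_s)` and
   `f_st = Atten(f_s, f_t, f_t)` — and fused with learnable scalar
   weights: `f_fusion = LN(α·f_ts + β·f_st)`. Baseline fusion strategies
   (`sum`, `cat`, `atten`) are available for ablations.
3. **Global feature extraction and classification (GFEM).** Multi-head
   self-attention (h heads of width k/h) over the fused sequence models
   long-range dependencies; a fully connected head maps the flattened
   global features to m logits, `ŷ = argmax(FC(f_g))`.

Training minimises cross-entropy with Adam and a step schedule that
halves the learning rate every 50 epochs; dropout 0.3 regularises the
classifier head. Evaluation follows the subject-wise protocol: trials
are pooled per subject and split by stratified five-fold
cross-validation (4:1 train:test), accuracy is reported as μ ± σ with σ
computed with the population divisor over folds, and per-channel z-score
statistics are always estimated on the training fold only (a leakage
guard enforces this).

Because no deep-learning framework is assumed, the package carries its
own small reverse-mode autodiff engine (`stcca._autograd`, `stcca.nn`)
with convolution, batch/layer normalisation, fused attention, dropout
and Adam — every layer's gradient is verified against finite differences
in the test suite.

## Worked example

Generate a synthetic four-class trial set (8 channels, 1 s at 256 Hz,
SNR 10, fully coupled spatio-temporal class structure), filter it, and
run the five-fold protocol with a reduced network (k = 16):

```python
from stcca import SynthConfig, generate_trialset, TrainConfig
from stcca.preprocessing import PreprocessConfig, apply_chain
from stcca.evaluation import cross_validate, stratified_kfold
from stcca.model import ModelConfig

ts = generate_trialset(SynthConfig(n_classes=4, n_channels=8,
                                   n_timepoints=256, sampling_rate=256,
                                   trials_per_class=20, snr=10.0,
                                   coupling=1.0, seed=7))
clean = apply_chain(ts, PreprocessConfig())   # 0.5-100 Hz band-pass, 50 Hz notch
plan = stratified_kfold(clean.labels, 5, seed=7)
mc = ModelConfig(n_classes=4, channels=8, timepoints=256,
                 sampling_rate=256, k=16, h=4)
report = cross_validate(clean, mc, TrainConfig(epochs=10, seed=7), plan,
                        robustness_fractions=(0.05, 0.10), robustness_seed=7)
print(report.summary())
```

prints

```
Cross-validation scheme: stratified_kfold
Per-fold accuracy (%): 100.00, 100.00, 100.00, 100.00, 100.00
Accuracy: 100.00 +/- 0.00 %
F1 score (macro): 1.0000
Confusion matrix (rows = true class):
     20     0     0     0
      0    20     0     0
      0     0    20     0
      0     0     0    20
Accuracy with 5% channels dropped: 100.00 %
Accuracy with 10% channels dropped: 100.00 %
```

— at SNR 10 the four oscillatory class templates are easily separable,
so the network recovers every held-out trial and stays robust when a
random 5–10% of channels are zeroed at test time. The fitted-model API
mirrors the usual build-then-fit pattern:

```python
from stcca import STCCAModel
res = STCCAModel(ts, k=16).fit(epochs=10, seed=7)
print(res.summary())        # parameter count, final loss/accuracy, schedule
labels = res.predict(ts)    # 1-based class labels
```

The same pipeline is scriptable from the shell
(`stcca simulate / preprocess / train / evaluate / ablate / report`);
every run directory contains a manifest that re-executes the run
bit-identically.

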