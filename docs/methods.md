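# Methods

## Signal model and problem setting

The package decodes a class label `y ∈ {1..m}` from a fixed-length EEG
trial `x ∈ R^{ch×t}` sampled at `fs` Hz. The intended application is
speech-related EEG (inner/imagined speech), where class-discriminative
information is carried jointly by *where* activity appears on the scalp
(spatial topography) and *how* it evolves in time (oscillatory
dynamics), and where the two are coupled rather than independent.

## Network

**Local feature extraction.** Two convolutional pathways, each
`AG(ELU(BN(Conv2(Conv1(x)))))` with valid convolutions, stride 1 and
bias-free kernels:

| stage | temporal-first pathway | spatial-first pathway |
|---|---|---|
| Conv1 | 1→k, kernel (1, ⌊fs/10⌋) | 1→k, kernel (⌊ch/2⌋, 1) |
| Conv2 | k→k, kernel (⌊ch/2⌋, 1) | k→k, kernel (1, ⌊fs/10⌋) |
| BN | one BatchNorm2d over the k maps | same |
| AG | AvgPool (4,4), stride = window | same |

Kernel-size divisions use floor division. The two orders yield
identically shaped maps for every montage. Exactly one batch-norm
follows the second convolution (matching the literal operator nesting
above, not one per conv); convolution biases are disabled because the
batch-norm absorbs them. If a feature map is smaller than the pooling
window in one direction, the window shrinks to the map size in that
direction (this only matters for very small montages, e.g. 8 channels,
where the post-conv height is 5).

**Mapping to sequences.** Attention operates on fixed 512-position × k
sequences. The pooled k×H×W map is flattened to H·W positions and
area-resampled (box resampling with fractional bin overlap) to 512
positions. This map is parameter-free, preserves the position mean
exactly, reduces to pure rearrangement when H·W = 512, and works for
both down- and up-sampling. A learned projection would be an equally
defensible reading of the architecture but would change the parameter
count; the parameter-free choice keeps the budget interpretable across
montages.

**Coupled cross-attention.** Scaled dot-product attention
`softmax(QKᵀ/√dk)V` with max-subtracted softmax; the 1/√dk scaling is
applied to the (small) query matrix, which is algebraically identical
and cheaper than scaling the 512×512 score matrix. Each direction
(temporal-queries-spatial and spatial-queries-temporal) has its own
affine Q/K/V projections (k→k, biases enabled; sharing is not assumed).
The fused sequence is `LN(α·f_ts + β·f_st)` with α, β unconstrained
scalars initialised to 1 (symmetric start) and layer normalisation over
the feature axis (eps 1e-5). No positional encoding is used anywhere,
so attention is invariant to permutations of key/value positions and
equivariant to joint permutations in self-attention.

**Fusion baselines** for ablation: `sum` (elementwise), `cat`
(feature-axis concatenation re-projected 2k→k so downstream shapes are
unchanged), `atten` (softmax-normalised scalar gates computed by a
linear map of the mean-pooled pair, applied as a convex combination).

**Global stage and classifier.** Multi-head self-attention with h heads
of width k/h (k divisible by h), concatenated and passed through an
output projection (standard practice; the bare concatenation reading
would merely drop one k×k map). The classifier flattens the 512×k
global sequence and applies dropout → affine(→256) → ELU → dropout →
affine(→m); predictions are the argmax with lowest-index tie-break.
The exact head architecture is not uniquely determined by the
architecture description it follows; the hidden width is exposed in the
configuration.

**Ablation variants.** `no_lfem` replaces the convolutional pathways by
fixed area-resampling of the raw trial to 512 positions (time-major
flattening for the temporal stream, channel-major for the spatial
stream) plus a learned 1→k width projection per stream, leaving the
fusion stage's contract untouched. `no_gfem` routes the fused sequence
directly to the classifier.

## Training protocol

Cross-entropy loss, Adam (β = 0.9/0.999, ε = 1e-8), step schedule
`lr·0.5^⌊epoch/50⌋`, dropout 0.3, shuffled mini-batches. Defaults not
determined by the protocol this follows: base learning rate 1e-3 (Adam
convention) and batch size 32; both are exposed in `TrainConfig`.
Weight initialisation is fan-in uniform from the run seed; weight init,
batch shuffling and dropout noise all derive from `TrainConfig.seed`,
so runs are bit-reproducible in single-threaded execution.

The network trains in float32 (the engine is dtype-preserving;
float64 is used in gradient-verification tests via
`stcca.nn.set_default_dtype`). Gradients of every operation are
verified against central finite differences.

## Evaluation protocol

* **Stratified five-fold CV** per subject (shuffled,
  class-stratified, 4:1); per-class test counts differ by at most one
  across folds.
* **Accuracy aggregation**: μ = mean over folds; σ uses the population
  divisor (the fold count), matching the aggregation formulas this
  implements literally.
* **F1**: macro-averaged (class-balanced; declared in report headers);
  classes with no support contribute 0 with a warning.
* **LOSO**: one fold per subject for cross-subject generalisation.
* **Channel dropout**: `round_half_even(fraction·ch)` channels (min 1)
  are zero-filled in every test trial — zeroing rather than removal
  keeps the spatial kernel geometry fixed at build time valid.
* **Wilcoxon signed-rank** (two-sided): zero differences dropped,
  midranks on ties; exact null distribution for n ≤ 25 computed by
  convolution over doubled integer ranks (equivalent to enumerating all
  2ⁿ sign assignments, including tied ranks), tie-corrected normal
  approximation without continuity correction beyond. The pairing unit
  is per-fold accuracies for the same data and fold.
* **Leakage guard**: z-score fitting inside a fold goes through
  `fit_fold_zscore`, which raises if any test index reaches the fit.
* **Parameter/FLOP counting**: learnable scalars are counted exactly;
  the FLOP figure counts conv/affine/attention multiply-accumulates
  only and is an internal relative measure (FLOP conventions vary too
  much across tools for meaningful external comparison).

## Synthetic data generator

No public generative model exists for this paradigm's signals, so the
generator is an explicit stand-in designed to exercise every pipeline
stage:

* **Class templates**: rank-1 spatio-temporal patterns
  `outer(s_c, w_c)` — unit-norm Gaussian spatial vectors and
  Hann-windowed sinusoidal bursts with class-specific frequency
  (≥ 2 Hz apart inside 4–30 Hz) and latency, scaled to ~10 µV peak.
* **Coupling** ∈ [0,1]: at 0 every class has its own topography and its
  own waveform (either marginal identifies the class); at 1
  topographies are shared between class pairs and waveforms between the
  complementary pairs, so only the joint pattern is class-specific.
* **Noise**: per-channel 1/f (pink) noise plus a 30%-amplitude
  channel-correlated common-mode component, giving the band-pass, notch
  and re-referencing stages realistic work.
* **SNR**: the template gain is calibrated against the realised noise
  power, so the achieved signal-to-noise power ratio equals the
  requested value by construction.
* Defaults (m=4, ch=8, t=256 at 256 Hz, SNR 10, coupling 1) define the
  benchmark conditions used by the reference experiments.

What the generator does **not** emulate: volume-conduction forward
models, ocular/muscle artifacts, non-stationarity across a session,
inter-subject variability beyond independent template draws, and any
true coupling between speech content and EEG dynamics. Passing the
synthetic benchmarks therefore demonstrates that the pipeline is
correctly wired and can learn coupled spatio-temporal structure — not
that real-data accuracies are reproduced.

## Reference experiments and their scale

The benchmark runs (`stcca.benchmarks`) are scaled for a single CPU
core: feature width k = 16 instead of 32, and roughly a dozen epochs
instead of 200 — on the SNR-10 benchmark training converges within ~6
epochs, so this is past convergence. The class-recovery run uses 50
trials per class with five-fold CV; its permuted-label chance control
uses 5 epochs (under the null there is nothing to learn and held-out
accuracy sits at chance from the first epoch). The fusion comparison
(coupled cross-attention vs. summation) uses 25 trials per class,
two-fold CV, 10 epochs, averaged over three seeds.

A caveat on the fusion comparison: on this generator the summation
baseline is as good as — sometimes better than — coupled
cross-attention. Both convolutional pathways see the same full trial,
so even at coupling = 1 each stream alone carries the joint class
pattern, and the rank-1 templates are linearly separable; the
conditions under which bidirectional cross-attention pays off on real
EEG (rich, distributed spatio-temporal dependencies) are precisely what
the stand-in generator lacks. The comparison machinery is exercised and
reported honestly rather than tuned to favour either strategy.

## Numerical choices and degenerate inputs

* Filters: 4th-order Butterworth band-pass applied forward-backward
  (zero phase); notch as second-order IIR, quality factor 30;
  polyphase rational resampling. The conditioning chain names neither a
  filter family nor a resampling method; these are declared choices.
* z-score: per channel pooled over (trials × time) of the training
  split; std floored at 1e-8 with a logged warning for constant
  channels.
* Softmax: max-subtraction (invariant to adding a constant per logit
  row). Layer/batch-norm eps 1e-5. ELU α = 1.
* Argmax ties: lowest index.
* ICA artifact removal is intentionally out of scope: the pipeline
  assumes pre-cleaned input (standard EEG toolchains own that step).

## Known limitations

* Pure-NumPy training is CPU-bound; the 512-position attention matrices
  dominate runtime (~50 ms per trial per epoch at k = 16). Full-scale
  runs (k = 32, 200 epochs, 128 channels) are possible but slow.
* One stacked attention layer per stage (the architecture as specified);
  no residual connections or feed-forward blocks.
* The parameter count of the full configuration depends on the
  classifier-head reading (see above) and is not calibrated against any
  external figure.
* LOSO on synthetic multi-subject sets measures generalisation across
  independent template draws, a much harsher condition than real
  inter-subject variability.
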