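# Methods

## Model

The classifier is a 1D convolutional network over fixed-length inputs:
187 samples × 1 channel for beat tasks, 3000 samples × 4 channels for the
rhythm task. A convolutional stem (32 filters, kernel 5, same-length
padding) expands the channel count, an evolving normalization–activation
(EvoNorm) layer follows, then four residual blocks with output widths
(64, 128, 192, 256), then flatten and a dense head (64 hidden units, ReLU)
ending in 5 softmax classes, 2 classes, or one sigmoid unit.

Each residual block multiplies two paths elementwise:

* **path A**: `MaxPool1D(2) → Conv1D(kernel 1)` — a pooled channel
  projection. Kernel 1 on this path makes the two path shapes agree for any
  choice of the main kernel.
* **path B**: `EvoNorm → Dropout(0.1) → Conv1D(kernel 5, stride 2) → SE`.
  The strided convolution is padded so it emits exactly `T // 2` steps,
  matching the pooled path (a symmetric padding with this property exists
  for every odd kernel at stride 2; it is computed at build time).

**EvoNorm** fuses normalization and nonlinearity. The S0 series (default)
is per-sample: `y = x·σ(v x) / sqrt(GroupVar(x)+ε) · γ + β`, with the group
variance over time and the channels of each group (8 groups; all channel
widths are multiples of 8) and per-channel parameters γ, β, v. The B0
series is batch-dependent: the denominator is the elementwise maximum of
the batch standard deviation per channel and `v·x` plus the per-sample
instance standard deviation; running batch variances (momentum 0.9) replace
the batch statistic at inference. S0 is the default because it is
independent of batch size, which suits small-batch CPU training; B0 is kept
behind the `evo_variant` flag. ε = 1e-5 everywhere.

**Squeeze-and-excitation** pools each channel over time (squeeze), passes
the pooled vector through `dense(C → max(1, round(0.25·C))) → ReLU →
dense(→ C) → sigmoid` (excitation), and rescales the channels by the
resulting weights in (0, 1). The ratio 0.25 is the pinned default.

**Ablation switches.** `use_evo=False` replaces every EvoNorm with a
parameter-free bypass (per-sample standardization by the global activation
standard deviation, then ReLU); `use_se=False` removes the gates entirely;
`use_gc=False` (training side) disables gradient clipping. Switching a
component off strictly reduces the parameter count, which the tests check.

All tensor math runs on an in-package reverse-mode automatic
differentiation engine over float64 NumPy arrays (`ecgkit.autodiff`):
a dynamically built tape with broadcasting-aware gradient accumulation and
custom adjoints for strided convolution (im2col/col2im) and max pooling.
Gradient correctness is verified against central differences in the tests.

Weights initialize from a fan-in-scaled uniform distribution with a seeded
generator, so model construction is reproducible; inference is
deterministic (dropout only acts in training).

## Losses

* Five-class beats: categorical cross-entropy computed in the
  log-sum-exp-stable form.
* Binary diagnostic beats: binary focal loss
  `FL(p_t) = −α_t (1−p_t)^γ log(p_t)` with α_t = 0.25, γ = 2 and
  `p_t = p` for positives, `1−p` otherwise. The scalar form applies the
  given α_t directly; the batch training loss uses the canonical
  α-balanced weights (α on positives, 1−α on negatives). With γ = 0 and
  α_t = 1 the focal loss reduces exactly to binary cross-entropy.
* Rhythm segments: binary cross-entropy.

Probabilities are clamped to [1e-7, 1−1e-7] before logarithms; batch
reduction is the mean.

## Training protocol

Adam (framework-default β₁ = 0.9, β₂ = 0.999, ε = 1e-8) with a staircase
schedule: learning rate 1e-3 multiplied by 0.1 at the milestone epochs —
(20, 40) over 50 epochs for the five-class task, (40, 120) over 150 epochs
for the binary diagnostic task. The rhythm task trains 25 epochs at batch
size 64 with a constant base rate plus reduce-on-plateau: when validation
loss fails to improve for 2 epochs the rate is multiplied by 0.9, and
training stops early after 5 non-improving epochs. ("Early-stopping decay"
is genuinely ambiguous; both the plateau factor and the stopping patience
are exposed as flags.)

Gradients are clipped by the **global** L2 norm across all parameters
jointly, threshold 0.001 — at this threshold nearly every step is rescaled,
so clipping acts as a normalized-gradient method; Adam's per-parameter
scaling makes training at this norm effective. Non-finite gradients skip
the step with a logged warning; a non-finite loss aborts with a diagnostic.

Class imbalance is handled by oversampling minority classes with
replacement to the majority count. The flag applies to training data by
default; oversampling validation data as well is available
(`oversample_val`) but defaulted off, since resampled validation sets bias
model selection. Test data are never resampled.

Stratified 5-fold (five-class) or 10-fold (binary) plans come from
scikit-learn's `StratifiedKFold` behind a wrapper that enforces the error
contract (a class smaller than k raises naming the class; k = 1 degenerates
to one fold with a warning). The 75/10/15 holdout split is stratified per
class with exact rounding; for the rhythm task the split is by *recording*
before segmentation so no recording contributes segments to two partitions.
Checkpoint selection keeps the best validation-accuracy epoch. With a fixed
seed the whole run is bitwise reproducible in single-threaded execution.

## Pre-processing

**Beat extraction** (beat tasks): resample to 125 Hz (polyphase, rational
ratio), split into 10-s windows, min-max normalize each window to [0, 1],
detect R peaks as local maxima with normalized amplitude ≥ 0.9 under a
200 ms refractory distance, set the nominal RR to the median peak spacing
in the window, cut each beat as `[peak, peak + 1.2·RR)`, truncate or
zero-pad to 187 samples. Windows are extended by the refractory span on
both sides for detection only, so peaks at window borders are not lost;
duplicates are removed. Windows with fewer than two peaks are skipped with
a warning. Each constant (window length, threshold, refractory, RR factor,
beat length, target rate) is an overridable parameter. Recordings shorter
than 2 s are rejected.

**Rhythm pipeline**: a bank of four linear-phase FIR band-passes
(Hamming window, 101 taps, default bands 0.5–5, 5–15, 15–40, 40–100 Hz,
applied forward-backward for zero phase) maps the single lead to four
channels covering P/T-wave, QRS, and high-frequency content at 300 Hz; the
bands and order are package defaults exposed in configuration, since only
the transform itself is pinned. Sliding windows of 3000 samples are cut at
offsets 0, step, 2·step, …, giving `floor((n−3000)/step)+1` segments; the
step is 50 for AF recordings and 500 for non-AF ones, which rebalances the
segment counts between classes. Recordings shorter than one window are
dropped and logged.

**Annotation mapping**: beat annotation symbols map onto the five AAMI
EC57 categories in the fixed order N=0, S=1, V=2, F=3, Q=4; both full
annotation names and the standard single-letter MIT-BIH symbols are in the
default map, and unknown symbols fall back to Q with a warning.

## Synthetic data conditions

Beats are sums of five Gaussian bumps (P, Q, R, S, T) on 187 samples,
min-max rescaled to [0, 1], with white Gaussian noise (default σ = 0.05
before rescaling) and small per-beat amplitude jitter (3%). The class
templates are fixed constants chosen for separability, not clinical
realism: S shifts all waves early (short pre-R interval), V widens the QRS
and removes the P wave, F is the N/V midpoint, Q is flattened and widened.
A nearest-centroid classifier separates the noise-free classes perfectly,
which is the intended property: the generator certifies the pipeline, it
does not certify clinical performance. Real ECGs differ in baseline wander,
electrode artifacts, inter-patient morphology variability, and class
overlap, so accuracy on synthetic data says nothing quantitative about
accuracy on clinical recordings.

Recordings are beat trains with configurable mean RR and uniform jitter;
ground-truth R-peak indices and labels are carried along. Rhythm strips at
300 Hz use mean RR 0.8 s; non-AF strips have ~1% RR variability and intact
P waves, AF strips suppress the P wave and rescale the RR deviations of the
underlying train to a coefficient of variation of exactly 0.25 — imposing
rather than sampling the variability, because the sample CV of a dozen
intervals fluctuates too widely to guarantee the AF/non-AF contrast at
every seed. All generators are pure functions of their arguments including
the seed.

## Problem sizes

The tests and the acceptance script run the generator-backed study at desk
scale, chosen as the package's reference conditions: 500 beats (100 per
class, noise σ = 0.05) trained for 30 epochs at batch 32 for the main run,
and 250 beats for 12 epochs per ablation configuration. At these sizes the
full model reaches 100% train and held-out accuracy on the separable
synthetic classes; the ablation runs demonstrate that all four
configurations train, not that the component ranking on clinical data
reproduces at this scale.

## Known limitations

* The default architecture constants (filter counts, kernel sizes, dropout,
  head width) are this package's choices where the design space was open;
  they are all single-line configuration changes.
* The NumPy engine is single-threaded and float64; it is sized for
  desk-scale experiments, not for training on the full clinical corpora.
* The B0 EvoNorm running-statistics update uses a fixed momentum of 0.9.
* Only additive Gaussian noise is modeled; no baseline wander or powerline
  interference.
* Lead selection for multi-lead records takes the named lead or channel 0;
  no lead-quality assessment.
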