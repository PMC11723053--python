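# Methods

This note documents the models, estimators and simulation assumptions
behind `mieog`, the defaults that matter, and what the test suite does and
does not establish.

## The classification model

The classifier is a 1-D convolutional network operating on epoched,
per-channel z-scored trials of shape `(channels, samples)`:

1. **Optional channel attention.** Adaptive average- and max-pooling
   collapse the time axis to one value per channel; both pooled vectors
   pass through a shared bottleneck (pointwise convolution `C → ⌈C/r⌉`,
   ReLU, pointwise back to `C`; reduction `r = 4` by default), are summed
   and squashed by a sigmoid into per-channel gates `g ∈ (0,1)` that
   multiply the input. The restoring convolution is zero-initialized so all
   gates start at exactly 0.5; a hotter initialization saturates the
   sigmoid and silences random channels before any learning happens.
2. **Multi-kernel temporal block.** Three parallel 1-D convolutions over
   time with kernels 3, 5 and 9 and 32 filters each (input depth =
   channels, length-preserving zero padding), concatenated to 96 feature
   maps, then ReLU and batch normalization. The activation-then-norm order
   is kept as the reference design describes it; a config flag switches to
   the more common norm-then-activation order (both train equivalently in
   our experiments).
3. **Depthwise stage.** A depthwise convolution (kernel 25, padding 7, one
   filter per map) shortens the time axis by 10 samples and uses `96·25 =
   2 400` weights instead of the `96²·25 = 230 400` of a full convolution.
4. **Depthwise-separable stage.** The same depthwise geometry followed by
   a pointwise (1×1) convolution that mixes the 96 maps (map count kept at
   96 throughout).
5. **Head.** Batch normalization, ELU, average pooling (size 8, a
   configuration default — the reference design does not state one),
   dropout (0.5), flatten, and a single dense layer to the class logits.

The network and its training loop are implemented directly in NumPy: each
layer carries an explicit backward pass, verified against central-difference
numeric gradients to ~1e-7 in the test suite; optimization is Adam
(lr 1e-3) on softmax cross-entropy. Training runs in single precision;
float64 is used where exact numerical checks matter.

## Training and evaluation protocol

One run: stratified 80/20 trial split, per-channel standardization with
train-set statistics, a fixed number of epochs, held-out accuracy recorded
after every epoch. The figure of merit is the **peak** test accuracy over
epochs. This reproduces the published protocol and is *optimistic* (it
selects a model on the test trace); an honest mode carves a validation
split out of the training data for peak-picking and reports the test set
untouched — off by default to match the protocol being reproduced. The
stratified split apportions per-class train counts by largest remainder so
that the total equals `round(0.8 · n_trials)` (576 trials → 461/115) while
class balance is preserved within rounding. Summary rows of accuracy tables
use the population standard deviation (÷N) and the midpoint median for even
counts — the only conventions under which the published per-subject tables
reproduce their printed summary rows.

## Channel-importance suite

* **Mutual information** between each EOG and each EEG channel, on the
  concatenated time series of all trials: plug-in estimate
  `I = H(X) + H(Y) − H(X,Y)` on an equal-width 2-D histogram (64 bins per
  axis, log base 2). Marginals are the row/column sums of the joint
  histogram, so symmetry and `I ≤ min(H(X), H(Y))` hold exactly. The
  plug-in estimator is positively biased by roughly `(bins−1)²/(2N ln 2)`
  bits; with ≥10⁵ samples per channel this is ≪0.01 bits.
* **CSP patterns.** Data are band-passed to 7–35 Hz (zero-phase FIR,
  order ≈ 3.3·fs/low). Per-trial covariances are trace-normalized,
  averaged within class, shrunk by `1e-6 · trace · I`, and the generalized
  eigenproblem `S w = λ R w` is solved; spatial patterns are the
  inverse-transpose of the filter matrix. With more than two classes,
  one-vs-rest contrasts are fit per class and the pooled (λ, pattern)
  pairs are re-ranked by **|log λ|** — the symmetric distance from the
  no-contrast eigenvalue λ = 1, invariant to swapping the contrast (λ and
  1/λ describe the same contrast from the two sides). Channel scores are
  the maximum absolute coefficient over the first five pooled patterns
  (columns normalized to unit length).
* **Permutation importance.** Whole trials of a single channel are
  shuffled across the trial axis (waveforms intact, trial–label pairing
  broken); the score is the drop in test accuracy averaged over 10
  shuffles. Computed on the held-out split.
* **Random search.** Subsets of k channels are drawn uniformly; each
  subset is trained/evaluated and its accuracy becomes the subset weight;
  a channel's score is the mean weight over the subsets containing it
  (its occurrence count is the denominator). Channels never drawn are
  flagged NaN rather than scored 0.
* **Attention gates.** The mean gate value per channel over all trials of
  a trained attention model. Because a single training run converges to
  one local optimum — and can legitimately gate off a channel whose
  information is partly redundant — the experiment driver
  (`attention_experiment`) trains independent replicates and combines
  their gate vectors weighted by each run's peak accuracy above chance
  (stability averaging). A replicate that reaches twice chance accuracy
  ends the loop early, since it dominates the weighted average anyway.

Wrapper methods accept any classifier handle; the default is a band-power
LDA (log-variance of 7–35 Hz filtered trials per channel, linear
discriminant), the classic fast baseline for oscillatory motor-imagery
signals. The deep model plugs into the same protocol.

## Synthetic data generator

Each channel is 1/f^a Gaussian background noise (default a = 1), built by
shaping the rFFT amplitudes of white noise so the target spectrum holds in
expectation; the spectral slope is recovered within ±0.3 by multitaper
log-log regression in the tests. On top of the background:

* **Class effects** are band-power modulations (an ERD/ERS analogue), not
  evoked waveforms. Every *informative* channel carries baseline mu
  (8–12 Hz) and beta (12–30 Hz) oscillations at amplitude
  `oscillation_amplitude × noise_sd` (default 0.5 — a rhythm whose band
  power is comparable to the local 1/f background). Class 0 is the
  unmodulated baseline; class k ≥ 1 scales the variance of its own band's
  oscillation on a contiguous *pair* of planted channels with opposite
  signs (power up on one, down on the other, multipliers `1 ± depth`).
  The balanced pair mimics lateralized sensorimotor modulation, keeps
  total power nearly class-independent — important because
  trace-normalized CSP otherwise converts a global power shift into a
  spurious contrast spread over all channels — and overlapping pairs make
  every planted channel contribute to some class margin, so wrapper and
  embedded methods have no incentive to prune one.
* **EOG channels** are built as independent background + ocular
  transients (Poisson-timed Hann pulses of 0.5–2 s at 5× background SD,
  all below ~4 Hz by construction) + a leakage term: `eog_leakage` times
  a distance-weighted mixture (weights 1, 1/2, 1/3, …) of the planted
  oscillation sources. The asymmetric weights keep the mixture's band
  power class-dependent, so EOG channels carry class information whenever
  leakage is non-zero — the mechanism is an admissible surrogate for the
  empirical observation that ocular channels record neural signal; no
  biophysical forward model is attempted.

The two presets reproduce the public benchmark layouts exactly (25
channels × 576 trials × 1000 samples at 250 Hz with 4 classes; 62 × 560 ×
800 at 200 Hz with 7 classes). Everything is reproducible bit-for-bit
from the config seed.

## Study sizes used in tests and the acceptance script

Planted-recovery experiments run on a scaled-down pooled-subject
recording: 12 channels (9 EEG + 3 EOG), 4 classes, 1-s epochs at 128 Hz,
modulation depth 0.8 and oscillation amplitude 0.8 on channels {2, 4, 6} —
a strong but physiologically plausible effect. Filter and wrapper methods
use 480 trials; the attention experiment uses 960 trials (the embedded
method trains a deep model and needs the larger pooled sample to converge
reliably) with 50-epoch replicates. Training-protocol tests use 2–4
channel datasets with 4-s epochs at 64 Hz, where a full-depth two-class
effect is essentially separable. These sizes are the package's choice of
desk-scale study conditions; the full-size protocol (500 epochs, five
splits, per-subject tables) is supported through the same functions.

## Numerical choices

* Multitaper PSD uses a normalized half-bandwidth of 4 (bandwidth
  `8·fs/n_samples` Hz) via DPSS tapers; dB conversion is `10·log10`.
* The band-pass is a linear-phase FIR applied forward-backward
  (zero-phase); out-of-band attenuation exceeds 20 dB one octave outside
  the band.
* CSP shrinkage default `1e-6 · trace`; a singular covariance without
  regularization raises an error advising more shrinkage.
* Importance rankings break score ties by ascending channel index, and
  NaN scores rank last, so reports are deterministic.
* All randomness flows from explicit integer seeds (`numpy` Generators);
  identical seeds give bit-identical datasets, splits and training traces.

## Limitations

* Peak-test-accuracy selection is optimistic by construction; the honest
  validation mode exists but is not the default because the default
  reproduces the published protocol.
* Attention-gate importance is the least stable of the five methods: gates
  reflect one trained optimum, and the stability-averaged experiment is
  required for reliable recovery even on synthetic data. Single-run gate
  vectors should be interpreted with care.
* The generator emulates second-order structure (spectra, band-power
  effects, leakage) but not waveform morphology, non-stationarity,
  inter-subject variability or genuine ocular-neural coupling; passing
  recovery tests shows the estimators work where the assumed structure
  holds, not that they will rank channels correctly on any real recording.
* The plug-in MI estimator is biased upward at small samples; bin count is
  exposed and the default (64) targets the ≥10⁵-sample regime of
  concatenated trials.
* Loading the public benchmark datasets requires the optional loader
  dependency and network access; all tests run on synthetic data.
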