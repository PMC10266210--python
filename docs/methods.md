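# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind `crossfatigue`, at the level of detail a user needs to
interpret results and extend the package.

## Problem setting

Two EEG datasets measure the same latent construct — operator fatigue on a
`[0, 1]` index — under different recording setups and annotation schemes.
The source domain has continuous index labels (a PERCLOS-like ocular
measure sampled on a fixed grid); the target domain has only behavioral
reaction times, which are reserved for assessment. The goal is a regressor
for the target domain trained without its labels, using (1) a
self-supervised pretext task that learns dataset-specific features and (2)
an MMD-regularized adaptation step that aligns the two domains in a learned
projection space while fitting the regression on the source.

## Label pathway

Reaction times map to the drowsiness index
`DI(τ) = max(0, (1−e^−(τ−τ₀))/(1+e^−(τ−τ₀)))` with `τ₀ = 1 s`; DI is zero
for any reaction at or faster than `τ₀`, increases monotonically, and
approaches 1 for very slow reactions, which suppresses the long right tail
of raw reaction times. Both modalities are reduced to a single `[0, 1]`
index before segmentation.

Annotations are anchor series: each anchor's value is held constant over
its interval (the first interval extends back to `span_start`, the last
forward to `span_end`), and a segment's label is the overlap-fraction-
weighted average of the stepwise label over the segment's time span. This
is an exact integral of a piecewise-constant function, so a segment lying
wholly within one interval receives exactly that anchor's value, and
overlap weights always sum to one. Whether inter-anchor values should be
held constant or linearly interpolated is ambiguous in principle; the
constant reading is implemented because it makes the single-interval case
an exact special case rather than an approximation.

Segmentation draws one uniform offset in `{0..T−1}` per pass (default
`T = 1024` samples = 8 s at 128 Hz), tiles non-overlapping `C×T` windows
from it, and discards a trailing partial window. During training the offset
is re-drawn every epoch, so successive epochs see shifted windows — a cheap
augmentation that also decorrelates windows from fixed noise patterns.

## Signal conditioning

Recordings pass through a zero-phase windowed-sinc (Hamming) band-pass of
1–50 Hz applied forward-backward, with the order targeting a ≈1 Hz
transition band and capped for short recordings, then polyphase
downsampling to 128 Hz. Montages are matched across datasets by the
one-to-one correspondence principle: the montage with fewer channels drives
the matching, exact names match first (case-insensitive), then a
configurable alias table of montage synonyms and nearest-electrode
pairings; with the default table the bundled 18-name and 32-name montages
yield 17 matched channels (one posterior midline channel has no partner and
is dropped).

Training segments are scaled by their whole-segment RMS (per-channel mean
removed). This removes absolute units but *keeps the relative channel
amplitudes*: the spatial gain pattern of a recording setup is one of the
main cues that distinguishes datasets, and per-channel z-scoring (also
provided, as `normalize` / `TrainSpec.normalization="zscore"`) erases it.

## Architecture

The extractor has three parts:

* **Spectral stem.** A trainable convolutional filter bank (17→16 channels
  for the `tiny` depth, kernel 33, stride 2) initialized as Gabor
  (modulated-Gaussian) band filters at log-spaced center frequencies
  2–40 Hz with random spatial mixing, followed by squaring, 250 ms average
  pooling at a 125 ms hop, `log`, and batch norm. The stem output is a
  learned log-band-power sequence. The squaring/log front end matters: a
  randomly initialized linear stem cannot expose band-power structure from
  RMS-normalized EEG (linear probes of such features carry essentially no
  label signal), which is the same observation that motivates the classic
  shallow band-power EEG networks.
* **Residual stages with CBAM.** Basic blocks (two 3-tap convolutions,
  batch norm, identity or strided 1×1 skip) for `tiny`/`resnet18`, 1-4-1
  bottlenecks with expansion 4 for `resnet50`. When attention is enabled,
  each block's residual branch passes through CBAM: channel attention
  (average- and max-pooled channel descriptors through a shared
  reduction-16 bottleneck MLP, summed, sigmoid) followed by spatial
  attention (channel-pooled average/max maps through a 7-tap convolution,
  sigmoid). Attention is multiplicative and shape-preserving; forcing its
  weights to one reduces a block exactly to its attention-free form.
* **GRU.** The final `C′×L′` map is read as an `L′`-step sequence by a
  single-layer GRU with 64 hidden units; the last hidden state is the
  segment feature. With the GRU ablated, global average pooling over time
  replaces it (feature dimension then equals `C′`).

Three heads sit on dropout-regularized (rate 0.25) features: a single-logit
domain discriminator (64→32→1), one or more alignment MLPs (64→64→64;
multiple heads' MMDs are summed), and the one-node regression layer. The
regression output is unbounded during training (MSE handles the range) and
clipped to `[0, 1]` only at evaluation.

All layers, including the convolutions and the GRU, are implemented on a
small NumPy reverse-mode autodiff engine (`crossfatigue.nn`), so training
is dependency-free, single-threaded deterministic, and bit-reproducible
given the seeds.

## Losses

MMD² is estimated in the biased (V-statistic) plug-in form
`mean(K_ss) + mean(K_tt) − 2·mean(K_st)`. The default kernel is linear, in
which case MMD² is exactly the squared distance between the two projected
sample means — the plug-in mean-embedding form in which the learned
alignment network itself plays the feature map φ. RBF kernels
(median-pairwise-distance bandwidth, or fixed σ) are available for a
nonparametric variant; the bandwidth is computed outside the gradient. The
adaptation objective is `MSE + α·MMD²` with `α = 0.3`; the pretext loss is
mean binary cross-entropy with source = 0, target = 1. Pre-training is
cooperative (extractor and discriminator minimize the same loss), not
adversarial: the point is to *extract* dataset-specific features, the
opposite of a gradient-reversal setup.

## Optimization

SGD with momentum 0.9 and weight decay 0.001 (added to the gradient), plus
global gradient-norm clipping at 5 — a stability measure for recurrent
layers and small noisy batches, not part of the original recipe. The
learning rate follows a linear warm-up over `warmup_epochs` (default 10)
from `lr_min` to `lr_max`, then
`lr_min + (lr_max−lr_min)(1+cos(π(e−w)/100))/2` with the 100-epoch cosine
half-period; defaults `lr_max = 0.05`, `lr_min = 0.001`. The schedule is
continuous at the junction and bounded by `[lr_min, lr_max]` everywhere.
Source and target batches are paired by independent shuffles zipped to the
shorter stream. The adaptation extractor is warm-started from the
pretrained weights; the `no_pretraining` ablation starts from random
initialization, which is the only reading under which pre-training can
matter.

Desk-scale runs (tests, demo) use the `tiny` depth with `lr_max = 0.01` and
24–80 epochs; the full-scale constants above remain the defaults of
`TrainSpec`. Cross-validation splits by *recording* (never by segment,
which would leak overlapping windows across folds) and repeats over seeded
runs; the report aggregates mean ± sd.

## Synthetic data generator

Each recording is a sum of four band oscillators — delta 2 Hz, theta 6 Hz,
alpha 10 Hz, beta 20 Hz, base amplitudes 8/6/6/4 µV — plus 1/f-shaped noise
(4 µV). The fatigue signature is monotone by construction: theta and alpha
amplitudes scale with `0.5 + f(t)` and beta with `1.5 − f(t)`, where `f(t)`
is the latent fatigue index. Oscillator phases are random per channel and
*diffuse* at 0.8 rad/√s: real band rhythms are only partially
phase-coherent, and without phase diffusion the stable inter-channel phase
pattern becomes a recording fingerprint that lets a network shortcut any
learning task by memorizing recordings.

The latent index is a clipped mean-reverting random walk (mean 0.5,
reversion 0.01 /s, volatility 0.03 /√s, start point ~N(0.5, 0.25) clipped):
it is nearly constant within one 8-s annotation interval but sweeps a wide
range of `[0, 1]` over a session, which is the timescale separation real
vigilance drifts show.

Labels: the source-like modality samples `f` every 8 s plus clipped
Gaussian noise (sd 0.02). The target-like modality draws event times
(≈1 per 6 s) and emits reaction times `τ = τ₀ + ln((1+f)/(1−f)) + noise`;
this link is the exact algebraic inverse of the DI transform, so at zero
label noise the DI of the stored reaction times reproduces `f` to machine
precision — a property the tests exploit.

The domain shift scales four differences between target and source, all
proportional to `shift`: per-channel gains (sd 0.25·shift, fixed per
configuration), noise level (×(1+0.4·shift)), noise spectral tilt
(+0.12·shift on the 1/f exponent), and oscillator amplitude
(×(1+0.15·shift)). At `shift = 0` the domains follow the same law; the MMD
of band-power features grows monotonically with `shift`.

What the generator does **not** emulate: eye-blink/EMG artifacts (the
emulated datasets are artifact-cleaned), volume-conduction correlation
structure between channels, non-stationary noise, inter-subject
variability, or any nonlinear EEG dynamics. Passing tests on this generator
therefore demonstrates that the pipeline's machinery — label plumbing,
alignment, optimization, evaluation — behaves as claimed under a controlled
covariate shift; it does not certify performance on real EEG.

## Numerical choices and degenerate inputs

* Discretization thresholds 0.35/0.7 use the half-open convention: awake
  `< 0.35`, fatigue `[0.35, 0.7)`, drowsy `≥ 0.7`; values are clipped to
  `[0, 1]` first. Zero-denominator metric cells report 0.
* Sample indices are 0-based; segment spans are half-open `[start,
  start+T)`.
* `DI(τ)` saturates to 1.0 in float64 for `τ − τ₀ ≳ 37 s`; physically
  meaningful reaction times are far below this.
* Constant channels z-score to zeros; an all-zero segment RMS-normalizes to
  itself.
* EDF output is 16-bit with the physical range rounded outward to the
  header's two-decimal capacity before digitization, bounding the
  round-trip error by one digitization step.
* Pretext held-out accuracy is computed on held-back *recordings* (25% per
  domain), never on segments of training recordings.

## Known limitations

* Desk-scale training (tens of recordings, hundreds of SGD steps) leaves
  the regression far from the band-power oracle; the acceptance checks are
  therefore directional (adapted vs. unadapted, with vs. without labels)
  rather than absolute.
* The `resnet50` depth is implemented and tested for construction and
  shapes but is not exercised by full training runs on CPU.
* The NumPy engine is single-threaded apart from BLAS matmuls; wall-clock
  scales linearly with epochs × batches.
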