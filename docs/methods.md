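# Methods

This note documents the models, the numerical choices, and what the shipped
synthetic benchmark does and does not establish.

## Problem setting

Motor-imagery EEG (MI-EEG) decoding classifies short multi-channel EEG
segments by the movement a subject imagined. The physiological signal is
event-related desynchronization/synchronization (ERD/ERS): imagining a
movement attenuates mu-band (8–12 Hz) and modulates beta-band (13–30 Hz)
power over the contralateral sensorimotor cortex. Cross-subject decoding is
hard because spatial mixing, gains, and spectral detail differ between
people, so a decoder trained on some subjects mis-transfers to another.

## The decoder

The model fuses two branches over a z-scored trial `X ∈ R^{C×T}`:

**Temporal stack (ASB + ICB residual layers).** Each of 3 layers computes
`X + LN(ICB(LN(ASB(X))))`. The adaptive spectral block (ASB) takes the
real FFT along time, forms the power spectral density `P = |F|²`, normalises
it by its per-trial maximum, and gates bins with a hard mask
`m = 1[P_norm > θ]`, where the threshold `θ = sigmoid(θ_raw)` is trained
through a straight-through sigmoid surrogate of width `τ = 0.02` (the hard
indicator has zero gradient; the surrogate width makes `θ` scale-free on the
max-normalised PSD). Two learnable complex filters act on the raw and the
gated spectrum, `F_int = W_G ⊙ F + W_L ⊙ (F ⊙ m)`, and the inverse real FFT
returns a same-length signal. Initialisation is near-identity
(`W_G = 1`, `W_L = 0`, `θ ≈ 0`), so an untrained stack passes signals
through. The interactive convolution block (ICB) gates a short-kernel and a
long-kernel convolution through GELU, `A1 = φ(c1)⊙c2`, `A2 = φ(c2)⊙c1`, and
fuses `A1 + A2` with a third convolution (kernels 2/8/4, dropout 0.5 after
gating).

Both FFTs are implemented as exact DFT matrix products, so the spectral
path is differentiated by the same reverse-mode engine as everything else
and the analysis/synthesis pair is an exact inverse (round-trip < 1e-10).

**Spatio-temporal branch.** Two same-padded temporal convolutions (F1 = 12,
F2 = 2·F1 = 24, kernel length K_E = 30), a full spatial collapse over the C
channel rows, then the square → average-pool → log band-power cascade of
shallow EEG ConvNets, dropout 0.5 and batch normalisation. The log is
clamped at 1e-7 so silent segments stay finite.

**Riemannian branch.** Per trial the channel covariance
`Cov = (1/N)Σ(x_t−μ)(x_t−μ)ᵀ` is shrunk by `s = 1e-3` toward
`(tr/C)·I` (3-channel and degenerate trials need the floor), whitened by the
inverse square root of its domain's geometric mean, and log-mapped to
tangent-space coordinates at the identity. Alignment is *per domain*
(source and held-out subject each use their own mean): it is unsupervised,
so applying it transductively to the unlabelled test subject leaks no
labels. The log-Euclidean mean (exp of the average matrix log) is the
default — non-iterative and deterministic; the affine-invariant Karcher
fixed-point mean is available and is what the congruence-invariance tests
exercise. Eigenvalues are floored at 1e-10 before any log/√. The aligned
matrix passes through parallel 2-D convolutions (F3 = 4 filters; kernels
1×1/3×3/5×5 for 22 channels, 1×1/2×2 for 3), each map is global-average
pooled, and the |kernels|·F3 concatenation is linearly projected to the same
width.

**Classifier and objective.** Branch features are concatenated, mapped to a
128-unit ReLU layer (the penultimate features), dropped out and classified
by a K-way softmax with cross-entropy. Cross-subject training adds
`λ · MMD²` between source-batch and target-batch penultimate features
(λ = 1 by default; a weighting "computed from the source labels" is
mentioned in the literature without a formula, so a constant with an
optional ramp is exposed). MMD² is the biased V-statistic
`mean(K_ss) + mean(K_tt) − 2·mean(K_st)` averaged over an RBF bank with
median-heuristic bandwidths (`σ₀ = sqrt(median(d²)/2)`, multipliers
0.25/0.5/1/2/4; bandwidths are constants of the batch, not differentiated).
The printed closed form of the estimator in the source literature
(1/m², 1/n² with a single cross term) does not reduce to a valid MMD; the
standard estimator matching the "distance between mean embeddings" prose is
implemented.

**Optimisation.** Adam (lr 1e-4, weight decay 0.075 added to the raw
gradient, conventional betas/eps) with batch 64 for 500 epochs on the real
datasets. Every convolution kernel's flattened L2 norm is renormalised to
≤ 2.0 after each step. The checkpoint with the lowest validation
*classification* loss is kept (comparable across λ), and that checkpoint is
what the test scores report. Validation is source-only in LOSO; target
labels are read by nothing but the final scoring (a test scrambles them and
asserts bit-identical training).

## Complexity reconciliation

The published structural table under-determines four things: the pooling
stride (a stride of 15 vs an output length of T/75), the spectral-filter
scope (per channel vs shared across channels), the ICB convolution type, and
how the Riemannian maps are flattened. `reconcile_complexity()` sweeps the
16-point discrete grid, ranking points lexicographically by how many of the
published parameter counts (0.198 M / 0.159 M) they reproduce at printed
precision and then by relative error; the winning dials then fix the
MAC-to-FLOP convention against the published 421.681 M / 57.752 M by the
same rule. The selected point — per-channel spectral filters, depthwise ICB
convolutions, pooled Riemannian features, stride 75, 1 MAC = 2 FLOPs, FFT
excluded — reproduces the 22-channel model exactly (197,857 parameters =
0.198 M) and both FLOP figures to 0.4 % and 0.07 %. No grid point
reproduces the 3-channel 0.159 M: with the same dials that model has
70,510 parameters, and the printed 22-vs-3-channel difference of 0.039 M is
inconsistent with every table-faithful instantiation (each component either
shrinks far more or far less when C drops from 22 to 3). The sweep report
is emitted by `rmetnet profile --sweep` and the discrepancy is reported,
not hidden.

FLOP counting is analytic from tensor shapes over all convolution and
linear layers; FFTs, when included, count `5·n·log₂n` per transform.
Complex filter entries count two trainable scalars.

## Synthetic benchmark

`synthetic_data` generates trials as
`gains ⊙ (M_s @ (pink + μ-osc + β-osc)) + white noise`: a 1/√f-shaped
pink background (flat below 1 Hz, unit variance), per-channel sinusoids
with trial-specific frequency and phase drawn uniformly inside each band
(avoiding degenerate coherence across trials), and ERD implemented by
multiplying the mu amplitude on the class-matched contiguous channel group
by `1 − erd_depth`. Inter-subject shift is a mixing matrix
`M_s = I + shift·G_s` with per-channel log-normal gains whose spread also
scales with `shift`, so `shift = 0` means identically distributed subjects
(an invariant the tests assert). White noise is scaled so the nominal mu
oscillation power sits at `snr_db`. One global seed expands through
counter-based `SeedSequence` keys into independent per-subject and
per-trial streams, making output independent of generation order.

Default conditions: 4 subjects, 2 classes, 40 trials/class/subject, 6
channels, 250 samples at 250 Hz, `erd_depth = 0.8`, `shift = 0.3`,
`snr = 10 dB`. Amplitudes are mu 1.0 / beta 0.5 — beta weaker than mu, as
in sensorimotor recordings.

What passing tests show: the pipeline recovers a planted, linearly mixed
band-power contrast across subjects, beats chance in LOSO transfer by more
than 3 binomial standard deviations, and the MMD penalty does not hurt
(directionally mirroring the published ablation). What they do not show:
performance on real EEG — the generator has no volume-conduction forward
model, no artifacts, no non-stationarity within trials, and far less
class overlap than real MI data.

## Desk-scale run sizes

Synthetic runs use a scaled-down preset (`synthetic-small`: F1 = 6,
F2 = 12, K_E = 15, one temporal layer, pool 25/25, hidden 64, learning rate
1e-3, no weight decay, 30 epochs) chosen so a full LOSO fold trains in
under a minute on one CPU while still reaching ≥ 0.9 accuracy on the
default generator. The full-size presets (`bciciv2a`, `bciciv2b`) carry the
published hyperparameters and are intended for runs on the real GDF
recordings.

## Degenerate inputs and tie-breaks

* z-score σ floored at 1e-8: constant channels normalise to zeros.
* Covariance shrinkage 0 on a singular trial raises rather than silently
  regularising.
* Cohen's kappa is defined as 0 when expected agreement is 1.
* Wilcoxon: zero differences dropped; all-zero gives (0, p = 1.0) by
  convention; exact null by rank-sum convolution for n ≤ 25 without ties,
  brute-force sign enumeration with ties up to n = 14, normal approximation
  with `Var = Σr²` above.
* Stratified splits give the rounding remainder to the largest fraction,
  keeping per-class proportions within one trial.
* `band_power` integrates the periodogram over `[f_lo, f_hi)`; a band whose
  upper edge is exactly fs/2 includes the Nyquist bin so band partitions
  satisfy Parseval exactly.

## Known limitations

* The 3-channel parameter figure cannot be reconciled (see above).
* The GDF loaders are thin wrappers over MNE and are exercised only on
  their error paths in the test suite; the printed per-subject trial counts
  (288, 480) are contracts of the loader, not tested against real files
  here.
* Training is NumPy on CPU; it is sized for the synthetic benchmark, and
  500-epoch runs on the full 22-channel preset are out of desk scale.
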