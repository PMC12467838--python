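# Methods

This note documents the models, conventions and numerical choices behind
`emgfusion`, the parameters that matter, and what the synthetic benchmark
does and does not demonstrate.

## Problem and pipeline

The package classifies trunk-motion intention from 6-channel surface EMG
(sEMG) of the back — left/right erector spinae, latissimus dorsi and
trapezius, recorded in the fixed channel order `[ES-L, LD-L, TR-L, ES-R,
LD-R, TR-R]` — into five movements: front side bending (FSB), left/right
side bends (BLS/BRS) and left/right twists (LT/RT). Downstream, the
predicted twist probabilities drive a threshold actuation policy for a
pneumatic lumbar-assist exoskeleton, and a separate statistical module
quantifies the assist effect (%MVC and a paired t-test).

Stages, in order: cleaning → active-segment detection → two parallel
feature paths (GAF images; windowed VMD/Welch feature sequences) →
dual-branch network with attention fusion → random-forest head.

## Cleaning and segmentation

* **Wavelet denoising** — 4-level `db2` decomposition; detail coefficients
  shrunk (soft by default) at the universal threshold `sigma*sqrt(2 ln N)`
  with `sigma` from the median absolute deviation of the finest detail
  level. Only the finest detail level is shrunk by default
  (`threshold_levels=1`): the denoiser targets the high-frequency noise
  floor, and db2's short filters leak in-band signal into coarser levels,
  so shrinking them measurably distorts band content (verified on an 80 Hz
  tone in white noise: shrinking all levels *increases* the RMS error
  against the clean tone, shrinking the finest level decreases it).
  `threshold_levels=None` restores classic all-level VisuShrink.
* **Band-pass** — 4th-order Butterworth over 10–100 Hz (the dominant sEMG
  band), applied forward–backward (`sosfiltfilt`) so activity onsets are
  not lag-shifted; the effective attenuation is the square of a single
  pass. 50 Hz power-line interference sits inside the pass band and is
  deliberately *not* notched — the cleaning chain is wavelet + band-pass
  only.
* **Segmentation** — trailing moving average (window `n = 128` samples,
  ~128 ms at 1 kHz) of the rectified signal; undefined (NaN) for the first
  `n−1` samples (no partial windows). Threshold default is
  `mean*(1+0.5) + 3*SD` of the moving-average series over a declared rest
  baseline (first 0.5 s when undeclared). The relative margin compensates
  for the window-correlated baseline underestimating the spread: without
  it, stationary rest noise occasionally trips the detector. Per-channel
  activity is OR-combined across channels; runs closer than 200 ms merge;
  runs shorter than 500 ms are dropped. A squared-signal energy convention
  is available by flag.

## GAF encoding

A segment is PAA-downsampled to `N = 64` points (32 in the reduced test
profile), min-max rescaled by
`x~ = ((x - max X) + (x - min X)) / (max X - min X)` into [-1, 1], mapped
to angles `phi = arccos(x~)` (timestamps kept as radii `t/N`, stored but
unused downstream), and expanded into `GASF = cos(phi_i + phi_j)` /
`GADF = sin(phi_i - phi_j)`. The rescale formula as written maps to
[-1, 1]; a `[0, 1]` compatibility mode (`rescale_mode="unit"`) exists
because both conventions circulate. A constant segment has no range and is
mapped to zeros (angle pi/2) with a warning. Each of the 6 channels yields
one GAF plane; the planes stack into the 6-plane input of the image
branch. GASF is the classification default; both kinds export.

Note the min-max rescale makes every plane amplitude-free: class
information expressed purely as per-channel amplitude does not survive GAF
encoding (see "What the benchmark shows" below).

## Feature sequences

Per active segment, windows of 0.25 s slide at 0.125 s (the benchmark
profile uses 0.5/0.25 s). Per window and channel, in fixed order:

* **MAV, RMS, WL, ZC** — mean absolute value, root mean square, waveform
  length, zero crossings. ZC uses a deadband of `0.01 * RMS` by default so
  noise does not inflate the count; a deadband of 0 restores the strict
  definition. The MDF/MPF naming follows the field's dominant convention —
  median frequency and mean power frequency — because the expansions
  attached to these initialisms are used inconsistently in the sEMG
  literature.
* **MDF, MPF** — from the window's Welch PSD (hann taper, `nperseg = 256`
  capped at the window length, 50% overlap). MDF uses the grouped-data
  median: cumulative power anchored at each bin's half mass with linear
  interpolation, which puts a single spectral line exactly at its own
  frequency and the median of two equal lines at their midpoint. MPF is
  the PSD-weighted mean frequency.
* **VMD band powers** — the window is decomposed into `K = 4` modes
  (bandwidth penalty `alpha = 2000`, dual step `tau = 0` for noise
  robustness, tolerance `1e-7`, at most 500 iterations); each mode's total
  Welch band power is one feature. The VMD is the standard frequency-domain
  ADMM: Wiener-like shrinkage of each mode spectrum around its center
  frequency, power-weighted center-frequency update, optional dual ascent;
  the input is mirror-extended by half its length on each side. Modes
  return sorted by ascending center frequency; non-convergence at the
  iteration cap is flagged, not raised. On a 10+80 Hz two-tone test the
  recovered centers are within 2 Hz and the mode-sum reconstruction
  residual is below 5%.

The flattened all-channel vector has length `n_channels * (6 + K)`.

## Classifier

* **Image branch** — VGG16 topology (conv blocks of depth 2-2-3-3-3 with
  3×3 kernels and 2×2 max pooling, two fully-connected layers), first
  layer accepting 6 GAF planes. Widths are configuration: the canonical
  [64, 128, 256, 512, 512]/[4096, 4096] full profile, and a reduced test
  profile [4, 8, 16, 32, 32]/[32, 32] with identical topology — the
  topology, not the capacity, is the architectural contract.
* **Sequence branch** — single-layer LSTM (hidden 128; 32 reduced) over
  the standardized feature sequence (per-feature mean/SD from the training
  windows); final hidden state projected to `d_model` (128; 32 reduced).
  Within a batch, sequences are front-padded with zeros (= the feature
  mean after standardization) so the final hidden state reflects real
  windows.
* **FRIM** — fine-grained relationship inference: multi-head scaled
  dot-product self-attention (`Q = W_Q x`, `K = W_K x`, `V = W_V x`,
  row-softmax of `Q K^T / sqrt(d_k)`, context = weights · V, heads
  concatenated), then feature-fusion linear + ReLU, residual add of the
  input, layer normalisation. It runs over 3 tokens — image embedding,
  sequence embedding, and a learned projection of their concatenation — a
  single-token mode is configurable.
* **Cross-attention fusion** — bidirectional single-token cross-attention
  with *tied* projections (image queries signal, signal queries image
  through the same weights), each direction through the same fusion/
  residual/normalisation machinery, the two outputs averaged. Tying makes
  the two directions provably identical for identical inputs.
* **Heads** — a linear soft-max head provides the differentiable
  cross-entropy objective for end-to-end Adam training; the *reported*
  probabilities come from a 100-tree random forest fitted post hoc on the
  fused embeddings of the best-validation checkpoint (vote fractions).
  This reconciles gradient training with a forest classifier: the forest
  itself is not differentiable.

All neural stages run on an in-package reverse-mode autograd over numpy
(finite-difference-checked in the test suite); layers are initialised from
an explicit seeded generator, so training is bit-reproducible.

**Training** — Adam, cross-entropy, initial lr 1e-4 with decay factor 0.1
every 10 epochs, at most 50 epochs, batch 40, dropout 0.5 — the
full-capacity defaults. A stratified 20% validation slice is carved from
the training set for checkpoint selection. The *reduced benchmark profile*
uses lr 5e-3, dropout 0.2, 25 epochs (decay step 15): with ~100 training
samples there are only 2–3 optimiser steps per epoch, so the full-scale
learning rate moves the weights negligibly and 0.5 dropout on a 32-dim
embedding is mostly noise; the desk-scale settings were chosen once for
convergence on separable data and then frozen.

**Ablation variants** — `vgg_only` (image branch + soft-max), `lstm_only`
(sequence branch + soft-max), `vgg_lstm_no_cam` (concatenation projection
+ FRIM, no cross-attention), `full`. All variants share the split,
preparation and seed.

**Actuation policy** — `P_left`/`P_right` default to the LT/RT class
probabilities (the mapping is configurable); above the 0.8 threshold the
left pneumatic muscle contracts by 70% or the right dilates by 30%;
otherwise no command. A no-activity recording yields uniform probabilities
flagged inactive and never commands.

## Synthetic generator

Amplitude-modulated band-limited Gaussian noise is the standard desk-scale
sEMG surrogate, chosen over motor-unit simulation for testability. Per
channel: unit-RMS Gaussian carrier band-limited to 10–150 Hz, multiplied
by `base_amplitude (300 uV) * gain[class, channel] * envelope`, where the
envelope is a raised-cosine rise (0.8 s), plateau, and fall over one 4 s
movement cycle padded by 1 s of rest on each side. The 5×6 gain matrix is
lateralised (bends load the loaded-side erector spinae, twists the
latissimus/trapezius); its values are arbitrary, chosen solely so classes
are separable, and a `separation` knob interpolates every row toward the
all-ones row (`separation=0` makes classes identical — the negative
control). Nuisances: 50 Hz sinusoidal power-line interference (20 uV),
ECG-like biphasic pulse train at 72 beats/min (50 uV), low-frequency
random-walk drift low-passed below ~2 Hz (100 uV RMS), white noise
(8 uV). Paired assist data draw a positive baseline power per subject and
muscle and apply a per-observation reduction `r ~ N(0.40, 0.05)` truncated
to [-1, 1] — the negative tail is admitted so a zero-mean reduction is a
true null; at the default parameters it is never reached.

What the surrogate does *not* emulate: motor-unit recruitment and firing
statistics, electrode-skin impedance drift, inter-subject anatomy, ECG
morphology, or movement-to-movement waveform structure beyond the
envelope. Consequently, a passing benchmark demonstrates that the pipeline
machinery — preprocessing, encoding, feature extraction, fusion, training,
inference — is correct and discriminates classes whose separability the
generator provides (largely via channel-amplitude patterns, which the
sequence branch captures); it does not certify accuracy on real
recordings. In particular, the GAF min-max rescale removes amplitude, so
the image branch alone is near chance on this surrogate even though the
fused model is not; on real sEMG, waveform structure carries class
information the image branch can use.

## Assist-effect statistics

Muscle load is the trailing 100 ms RMS envelope; per trial the envelope is
mean-centered and rectified, its peak is the peak power, and the peak
normalises against the MVC benchmark (largest of three repetition RMS
peaks) as `%MVC = action RMS / MVC RMS * 100`. The paired t-test uses
`t = dbar / (s_d / sqrt(n))` with the n−1 sample SD — required to
reproduce the reference summary t(40, 5, 8) ≈ 22.627, df = 7 — and a
two-sided p by default (one-sided by flag). Zero-variance differences are
reported as a degenerate no-effect case, not an exception. No
multiple-testing correction is applied across muscles.

## Determinism and seeds

One global seed fans out to per-stage seeds via
`numpy.random.SeedSequence([seed, stage_index])` with fixed stage indices,
so stages are independently reproducible and a rerun of the CLI chain with
the same config and seed is byte-identical (manifests record command,
seed, and config digest; they contain no timestamps in compared outputs).

## Benchmark problem sizes

The recognition benchmark uses 24 trials per class (96 train / 24+ test
after the stratified 80/20 split) at 1 kHz with the reduced model profile;
the negative control uses 12 per class at 10 epochs; the ablation table 10
per class at 10 epochs. Unit tests run the same machinery at 500 Hz with
5–12 trials per class. These sizes were chosen once as the smallest at
which the properties of interest are stable.

## Known limitations

* The image branch is untestable for positive discrimination on the
  surrogate data (amplitude-free GAF planes), only for mechanics.
* VMD center frequencies can merge for K larger than the number of
  distinct spectral concentrations; the reconstruction residual bound is
  meaningful only for band-limited inputs.
* The actuation mapping from 5-class probabilities to P_left/P_right is a
  convention (twist classes by default) and should be revisited against
  hardware semantics.
* 50 Hz interference inside the pass band survives cleaning by design of
  the stated chain.
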