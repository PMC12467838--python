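# emgfusion

Multimodal surface-EMG (sEMG) trunk-motion intention recognition, built for
work on lumbar-assist exoskeletons: it turns 6-channel back-muscle
recordings (left/right erector spinae, latissimus dorsi, trapezius) into one
of five movement intentions — front side bending (FSB), left/right side
bends (BLS/BRS), left/right twists (LT/RT) — plus the statistics used to
quantify how much an exoskeleton unloads those muscles.

The pipeline:

1. **Cleaning** — 4-level `db2` wavelet threshold denoising, then a
   zero-phase 4th-order Butterworth band-pass over the dominant 10–100 Hz
   sEMG band.
2. **Active-segment detection** — a trailing moving average of the
   rectified signal, `MAS_t = (X_{t-n+1} + … + X_t)/n`, thresholded against
   a rest baseline.
3. **Gramian Angular Field imaging** — each channel segment is rescaled to
   [-1, 1], mapped to angles `φ = arccos(x̃)`, and expanded to
   `GASF_{ij} = cos(φ_i + φ_j)` / `GADF_{ij} = sin(φ_i − φ_j)`; the six
   planes stack into a VGG16-topology convolutional branch.
4. **VMD/Welch feature sequences** — per sliding window and channel: MAV,
   RMS, waveform length, zero crossings, median and mean power frequency,
   and the Welch band power of each of K = 4 variational modes; the
   sequence feeds an LSTM branch.
5. **Attention fusion** — a fine-grained relationship inference module
   (multi-head self-attention: softmax(QKᵀ/√d_k)·V with a fused
   linear+ReLU, residual and layer norm) over the branch embeddings,
   bidirectional cross-attention between the two modalities, and a random
   forest fitted on the fused embedding for the reported class
   probabilities. Training is end-to-end Adam + cross-entropy through an
   auxiliary soft-max head.
6. **Downstream** — a threshold actuation policy (twist probability > 0.8
   contracts/dilates the corresponding pneumatic muscle) and an
   assist-effect module: sliding RMS envelopes, %MVC = action RMS / MVC
   RMS × 100, and the paired t-test `t = d̄/(s_d/√n)`.

A seeded synthetic generator (amplitude-modulated band-limited Gaussian
carriers with class-dependent lateralised activation envelopes, plus 50 Hz
power-line interference, ECG artifacts, baseline drift and white noise)
makes every stage testable without any recorded data. The neural stages run
on a small, finite-difference-verified numpy autograd included in the
package; no GPU or deep-learning framework is required.

See `docs/methods.md` for modelling conventions, parameter defaults and
limitations.

## Worked example

```python
import numpy as np
from emgfusion import (generate_trial, MovementLabel, preprocess_recording,
                       segment_recording, encode_stack, build_feature_sequence,
                       vmd, paired_t_summary)

rec = generate_trial(MovementLabel.LT, fs=1000.0, seed=42)
clean = preprocess_recording(rec)
seg = segment_recording(clean)[0]
print(f"trial: {rec.duration:.0f} s, active segment "
      f"{seg.start/rec.fs:.2f}-{seg.end/rec.fs:.2f} s")

stack = encode_stack(clean.signal[:, seg.start:seg.end], size=64)
print(f"GAF stack: {stack.shape}, range [{stack.min():.2f}, {stack.max():.2f}]")

fseq = build_feature_sequence(clean, seg, window_len=0.5, stride=0.25)
print(f"feature sequence: {fseq.vectors.shape[0]} windows x "
      f"{fseq.vectors.shape[1]} features")
res = vmd(clean.signal[0, seg.start:seg.start + 1000], K=4, fs=1000.0)
print("VMD centers (Hz):", np.round(res.center_freqs, 1))

t, df, p = paired_t_summary(40.0, 5.0, 8)
print(f"assist paired t-test: t = {t:.3f}, df = {df}, p = {p:.2e}")
```

prints

```
trial: 6 s, active segment 1.22-4.93 s
GAF stack: (6, 64, 64), range [-1.00, 1.00]
feature sequence: 13 windows x 60 features
VMD centers (Hz): [21.5 41.4 63.2 83.8]
assist paired t-test: t = 22.627, df = 7, p = 8.34e-08
```

The 6 s trial carries one 4 s movement cycle; the detector brackets it. The
GAF stack is one 64×64 plane per muscle. Each 0.5 s window contributes
6 channels × (4 time-domain + 2 spectral + 4 VMD band powers) = 60
features. The four VMD center frequencies tile the 10–100 Hz band of the
cleaned noise-like signal. The t-test reproduces the reference with/without
exoskeleton comparison: a mean 40% activation drop with SD 5 percentage
points over 8 subjects is overwhelmingly significant.

Training and classification run through the same API (`generate_dataset`,
`prepare_samples`, `train_on_samples`, `TrainedModel.predict`) or the CLI:

```bash
emgfusion --seed 1 simulate dataset --n-per-class 10 --out data/
emgfusion --seed 1 train --data data/ --profile reduced --out run/
emgfusion predict --model run/ data/test/FSB-000.csv
emgfusion actuate --p-left 0.9 --p-right 0.05
emgfusion assist-eval --summary 40,5,8 --out assist/
```

Every subcommand writes a manifest (command, seed, config digest) that
suffices to re-run it exactly; identical seeds give byte-identical metrics.

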