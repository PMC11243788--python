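# Methods

## Problem and model

`emgknee` estimates the knee flexion trajectory of each gait cycle from
multichannel surface EMG (sEMG) recorded during walking. Muscle activity
precedes the resulting joint motion by tens to hundreds of milliseconds, so
sEMG envelopes carry predictive information about the knee angle that a
sequence model can exploit — the basis for intent estimation in wearable
robotics.

The estimator is an encoder–decoder recurrent network with Bahdanau
(additive) attention, referred to as GRU-AM:

- **Encoder.** Each gait cycle is time-normalized to L = 100 samples per
  channel and tiled into non-overlapping 20-sample segments, ordered
  time-window-major / channel-minor. Each segment is one encoder time step,
  so M = (L/20) × n_channels (40 steps for 8 muscles, 30 for 6). A
  single-layer GRU of hidden size 100 consumes the segment sequence.
- **Attention.** At decoder step t, alignment scores
  `score(j,t) = Vaᵀ tanh(Ua s(t−1) + Wa h(j))` are softmax-normalized over
  the M encoder states and the context `c(t) = Σⱼ α(j,t) h(j)` is their
  convex combination. The alignment model width is 64 by default (`attn_size`);
  the score is linear in a tanh feature of the projected states, so the
  context always lies in the convex hull of the encoder states.
- **Decoder.** A GRU cell of hidden size 100 consumes `[ŷ(t−1); c(t)]` with
  previous state s(t−1); s(0) is the final encoder state and ŷ(0) = 0. The
  output is `sigmoid(wᵀs(t) + b)` on a [0, 1] angle scale, de-normalized to
  degrees with training-set min/max bounds. The attention-free baseline
  (GRU) is identical except `c(t)` is replaced by the final encoder state at
  every step.

Training is full-batch ADAM (learning rate 1e-3) on element-wise binary
cross-entropy between the sigmoid outputs and min–max-normalized angles;
BCE on a bounded regression target is unconventional but well-defined, and
mean-squared error is available via `loss="mse"`. After every epoch the
free-running training RMSE in degrees is computed; training stops when it
falls below 15° or at 10,000 epochs, whichever first.

**Free-running decoding during training.** The decoder is fed its own
previous output ŷ(t−1) during training (no teacher forcing, configurable
via `teacher_forcing`). We measured both regimes on a synthetic dataset in
which a single designated channel drives the angle: with an identical
budget, teacher-forced training reached test RMSE 15.1° / CC 0.74 while
free-running training reached 5.5° / CC 0.996. Teacher forcing trains a
one-step-ahead predictor that leans on the ground-truth previous sample and
largely ignores the EMG context; at inference, where only its own outputs
are available, it degrades sharply (exposure bias). Since the estimator is
always used free-running, training matches that regime.

All network arithmetic (GRU cells, attention, ADAM, backpropagation) is
implemented in the package on top of numpy via a small reverse-mode
automatic-differentiation tape (`emgknee._autodiff`); gradients are
verified against central finite differences in the test suite. Everything
is float64 and bit-reproducible from the configuration seed.

## Signal conditioning

Raw EMG is conditioned per channel by: Hampel outlier removal (20-sample
window; a sample is replaced by its window median when it deviates more
than 3 × 1.4826 × MAD; with strict inequality, constant windows are never
flagged) → zero-phase 4th-order Butterworth band-pass, 50–190 Hz →
full-wave rectification followed by a 50-sample centered moving average →
consecutive peak (sliding max) and RMS envelope detectors over 50-sample
windows → zero-phase Butterworth low-pass at 6 Hz. The band edges, Hampel
window and rectification window are the published operating points; the
6 Hz cutoff is a conventional linear-envelope choice and the Butterworth
family/order is ours (zero-phase filtering avoids envelope lag that would
corrupt EMG–angle timing). All sliding windows truncate at signal
boundaries so every stage preserves length.

## Gait processing

Cycles span consecutive `foot_contact` events of one side (right by
default); cycles shorter than 0.2 s or longer than 5 s are discarded with a
warning. Each cycle is linearly interpolated onto L = 100 points — a fixed
per-cycle length is forced by the 5 × 20-sample segment structure. The
train/test split is chronological (first 60% of strides train) to avoid
temporal leakage between adjacent strides; per-channel EMG min/max and
angle min/max normalization bounds are computed on training cycles only and
travel with the fitted model thereafter.

## Experiment protocols

- **Comparison** trains GRU-AM and the GRU baseline with matched seeds;
  the two arms differ only in `use_attention`.
- **Ablation** retrains from scratch (shared seed) with each channel
  removed and ranks channels by the increase in mean test RMSE; retraining
  isolates a channel's informational contribution rather than the trained
  model's reliance on it.
- **Transfer** pretrains on a 6-channel source dataset restricted to the
  shared muscle set (TA, MG, SL, VL, RF, MH), then personalizes by
  warm-start training on the first 10 subject strides.
- **Sequential (cyclic) learning** is prequential: each stride is estimated
  and scored before entering the buffer; after every 3 strides the model is
  fine-tuned (warm start) on all strides seen so far, capped at 50 epochs
  per update or the 15° rule, whichever first. The per-update budget is our
  choice, consistent with bounded per-cycle compute in on-line use. The
  logged per-stride RMSE series yields the convergence rate — the slope of
  the line joining the first and last stride's RMSE, in degrees per stride.
  Multi-visit adaptation chains sequential runs with model state carried
  over.

## Metrics

RMSE (degrees), Pearson CC, NRMSE (RMSE over the measured range), and an
SNR in dB defined literally as `10·log10(mean θ² / mean θ̃²)` — the
published form, which compares measured and estimated signal powers rather
than signal to error power. Because that definition is atypical, the
conventional error-based SNR is available via `mode="error"`; the literal
form is the default.

## Synthetic gait generator

No public recording accompanies the estimation task at the stated channel
sets, so the package ships a generator whose defaults embody the study
conditions and whose internals provide exact ground truth.

- **Spatiotemporal structure.** Per stride, gait speed and step length are
  drawn from preset normal distributions and stride duration follows as
  2·step/speed (clipped to [0.3, 4.5] s). Presets: `hv8` (8 channels,
  1000 Hz EMG, speed 0.91 ± 0.04 m/s, step 0.52 ± 0.02 m, 60-stride
  trials), `shared6` (the 6-channel shared-muscle subset at the same
  healthy profile), and `cp6` (6 channels at 2000 Hz, crouch-gait template,
  low SNR, three visit profiles with speeds 0.14 ± 0.03, 0.37 ± 0.16 and
  0.52 ± 0.06 m/s).
- **Knee-angle template.** Baseline flexion plus two periodic Gaussian
  waves: a small stance-flexion wave and a large swing-flexion wave
  (healthy: 5° baseline, 20° stance peak, 60° swing peak; crouch: 30°
  baseline, 38° stance, 55° swing with a damped swing wave).
- **Muscle envelopes.** Sums of periodic Gaussian bursts at standard gait
  timings (TA at contact and in swing, MG/SL late stance, PL/HL mid-late
  stance, RF/VL at loading with an RF pre-swing burst, MH terminal swing),
  with per-stride multiplicative amplitude jitter (SD 0.08 healthy, 0.20
  CP) and a small tonic baseline.
- **EMG-to-angle coupling.** The angle is a fixed non-negative linear
  combination of envelopes lagged by a 40 ms electromechanical delay,
  restricted to the knee flexor/extensor drivers (TA, MG, RF, VL) and
  calibrated once per preset by Tikhonov-regularized non-negative least
  squares against the template. EMG genuinely precedes and drives the
  motion, and per-stride envelope jitter propagates into per-stride angle
  variation that the estimator must read from the EMG. `driver_muscles()`
  builds a variant in which a single designated channel carries all the
  coupling, giving the ablation analysis an exact ground truth.
- **Raw EMG.** Envelope × band-limited (60–180 Hz) zero-mean unit-RMS
  carrier noise, plus an additive band-limited noise floor (RMS 0.05
  healthy, 0.25 CP, scalable via `noise_scale`) and sparse ±8×-amplitude
  motion-artifact spikes (rate 1e-4) that exercise the Hampel stage.
  `cp_degrade` divides the envelope-to-noise power ratio by `snr_scale` and
  inflates per-stride amplitude variability by `variability_scale` on an
  existing trial, keeping the stored ground truth consistent; stride-timing
  variability is a property of the generating profile.

What the generator does *not* emulate: electrode-shift and cross-talk
effects, spectral changes with fatigue, terrain variation, force-plate or
marker data, and the non-stationarity of real pathological EMG beyond
amplitude jitter and noise level. Passing tests therefore demonstrate the
pipeline's correctness and the estimator's behavior under controlled,
learnable conditions — not clinical performance on human data.

## Numerical choices and problem sizes

- Glorot-uniform initialization seeded from the config; full-batch
  training (datasets are tens of strides, and full batches keep runs
  bit-deterministic).
- Min–max spans of zero (constant channel) are replaced by 1 to avoid
  division by zero; the Hampel rule uses strict inequality so zero-MAD
  windows flag nothing that equals the median.
- Time-series CSVs print 12 significant digits (round trips are well below
  1e-9 absolute at gait magnitudes); rates are inferred from the median
  time step and must agree with declared rates within 1%.
- Tests and example protocols run on scaled-down problem sizes (12–24
  strides, hidden sizes 8–32, capped epochs) chosen to exercise every code
  path at desk scale; the training-termination check runs the full
  configuration (60 strides, hidden 100, 15°/10,000-epoch rule).

## Known limitations

- The default choice of BCE for a regression target is preserved for
  fidelity to the published training recipe; it weights errors
  non-uniformly across the angle range.
- The literal SNR definition is scale-sensitive (a perfect estimate scaled
  by 10 scores −20 dB); use `mode="error"` for a conventional figure.
- The attention-free baseline shares the training loop, so comparisons
  reflect the attention mechanism only, not tuning effort per arm.
- Sequential learning retrains on the accumulated buffer; no forgetting or
  drift-tracking mechanism is implemented (a sliding-window buffer is left
  to configuration of the caller).
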