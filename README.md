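# emgknee

Knee-angle estimation from surface EMG during walking, built around an
attention-based GRU encoder–decoder (GRU-AM), with the full pipeline
needed to use and evaluate it: signal conditioning, gait-cycle
segmentation, evaluation metrics, channel-ablation sensitivity analysis,
transfer and sequential (cyclic) learning protocols, and a synthetic gait
simulator with exact ground truth.

**Who it is for.** Researchers in biomedical signal processing and
neurorehabilitation who want a tested, reproducible reference
implementation of sEMG-to-kinematics estimation — for example as an intent
estimator for wearable knee exoskeletons — and a controlled synthetic
test bed for recurrent EMG decoders.

## The model

Each gait cycle (foot contact to next same-foot contact) is time-normalized
to L = 100 samples and tiled into 20-sample EMG-envelope segments, ordered
chronologically across channels: M = (L/20) × n_channels encoder steps
(40 for 8 muscles, 30 for 6). A GRU encoder (hidden size 100) consumes the
segments; at each of the L decoder steps a Bahdanau attention block forms

    score(j, t) = Vaᵀ tanh(Ua s(t−1) + Wa h(j))
    α(j, t)     = softmax_j score(j, t)
    c(t)        = Σ_j α(j, t) h(j)

and a GRU decoder consumes [ŷ(t−1); c(t)] to produce the next hidden state
s(t); the knee angle is sigmoid(wᵀs(t) + b), de-normalized to degrees with
training-set bounds. Training is full-batch ADAM on binary cross-entropy
over min–max-normalized angles and stops when the free-running training
RMSE drops below 15° (or at 10,000 epochs). The attention-free baseline
replaces c(t) with the final encoder state. The recurrent network,
attention and optimizer are implemented in-package on a small numpy
reverse-mode autodiff tape (gradients are finite-difference-verified in the
test suite); everything is bit-reproducible from a seed.

See `docs/methods.md` for the conditioning chain, the gait processing, the
experiment protocols and the synthetic generator.

## Worked example

```python
import emgknee as ek

# 12 strides of the 8-channel healthy walking preset, known ground truth
trial = ek.make_presets()["hv8"].synthesize(n_strides=12, seed=1)

emg, angle = ek.align_streams(trial.emg, trial.angle)
conditioned = ek.condition(emg)                       # Hampel→bandpass→…→6 Hz
cycles = [ek.time_normalize(c, 100)
          for c in ek.split_cycles(conditioned, angle, trial.events)]
dataset = ek.make_dataset(cycles, train_frac=0.6)     # chronological 60/40

cfg = ek.GruAmConfig(hidden_size=32, attn_size=32, seed=0,
                     rmse_stop=5.0, max_epochs=300)
results = ek.KneeAngleGRU(dataset, cfg).fit()
print(results.summary())
print(results.evaluate(dataset.test_cycles)[["rmse", "cc"]].mean())
```

Output:

```
Knee-angle estimator results
============================================================
Model:              GRU-AM
Channels (8):       TA, MG, SL, PL, HL, RF, VL, MH
Encoder steps M:    40
Decoder steps L:    100
Hidden size:        32
Trainable params:   13537
Loss:               bce
Epochs run:         191
Stop reason:        rmse
Final loss:         0.473541
Final train RMSE:   4.98 deg
Angle bounds:       [8.32, 62.29] deg
rmse    5.401423
cc      0.963344
```

Training stopped when the free-running training RMSE crossed the requested
5° target (191 epochs); the fitted estimator reconstructs held-out knee
trajectories to 5.4° RMSE with CC 0.96 at this deliberately small problem
size, recovering both the stance and swing flexion waves. `results.estimate_cycle(cycle)` returns one 100-sample trajectory in
degrees; `ek.compare_models`, `ek.ablate_channels`, `ek.pretrain_transfer`,
`ek.personalize`, `ek.sequential_learn` and `ek.progressive_visits` drive
the experiment protocols.

The same pipeline is scriptable from the shell:

```
emgknee simulate --preset hv8 --strides 12 --seed 1 --out run/sim
emgknee preprocess --manifest run/sim/manifest.yaml --out run/pre
emgknee segment    --manifest run/pre/manifest.yaml --out run/seg
emgknee train      --data run/seg --max-epochs 150 --out run/model
emgknee estimate   --model run/model --data run/seg --out run/pred.csv
```

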