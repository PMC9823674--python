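# myogait

Estimation of lower-extremity muscle activity in gait from wearable
inertial measurement units (IMUs), using feedforward and LSTM neural
networks.

## The problem

Surface electromyography (EMG) tells you *when* and *how strongly* a
muscle fires during walking, but EMG electrodes are impractical outside
the lab. Body-worn IMUs are cheap and wearable. `myogait` learns the
mapping from the signals of four IMUs (trunk, thigh, shank, foot — 24
channels of 3-axis acceleration and angular velocity) to the activation
envelopes of nine lower-extremity muscles:

gastrocnemius, tibialis anterior, soleus, vastus medialis, vastus
lateralis, rectus femoris, biceps femoris, semitendinosus, gluteus
medius.

Signals are cut into gait cycles (heel strike to heel strike), resampled
to 101 points (0–100 % of the cycle), and min–max normalized per cycle.
One regressor per muscle maps the 101×24 IMU block to the 101-point EMG
envelope. Two architectures are provided — a feedforward network on the
flattened block and a stacked LSTM over the 101-step sequence — both
implemented directly in numpy (no deep-learning framework required),
trained with Adam, dropout and early stopping. Agreement is scored with
nRMSE, Pearson r, and peak timing/amplitude errors (ΔTp, ΔEp), reported
as mean ± SD per muscle.

Because no EMG/IMU recordings ship with the package, it includes a
synthetic gait-data generator with muscle burst timing taken from the
standard gait literature and a construction that couples the IMU
channels to the muscle activations, so the whole pipeline is exercised
and tested end to end with known ground truth. See `docs/methods.md`
for the model, the generator, and all numerical choices.

## Quick start (CLI)

The `myogait` command runs the pipeline against a run directory; each
stage writes its artifacts there and is skipped on rerun if its inputs
are unchanged.

```bash
# everything: simulate -> preprocess -> split -> train -> predict
#             -> evaluate -> reconstruct
myogait run-all --run-dir run --seed 1

# or stage by stage, optionally from a YAML config
myogait simulate   -d run -c config.yaml
myogait preprocess -d run
myogait split      -d run --split-by stride
myogait train      -d run -a lstm -m soleus -m tibialis_anterior
myogait predict    -d run
myogait evaluate   -d run
myogait reconstruct -d run
```

`run/report.csv` then holds one row per architecture × muscle × group
(test and unseen subject) with `nrmse`, `r`, `delta_tp`, `delta_ep` as
mean ± SD. A YAML config may override any block (`signal`, `split`,
`model`, `synthetic`); unknown keys are rejected. The effective config
is written into the run directory.

## Worked example (Python API)

```python
import numpy as np
import myogait as mg
from myogait import nn

# a synthetic walking study: 4 subjects x 3 trials x 60 strides
study = mg.generate_study(seed=1)
samples = mg.build_samples(study.trials, study.muscles)
print(len(samples))                      # 720 gait cycles

split = mg.split_dataset(samples, seed=1)          # 80:15:5
print(len(split.train), len(split.validation), len(split.test))
# 576 108 36

cfg = nn.ModelConfig(architecture="lstm", hidden_layers=2,
                     hidden_units=64, learning_rate=3e-3,
                     batch_size=128, max_epochs=40,
                     early_stop_patience=8, seed=0)
est = nn.build_estimator(cfg, (101, 24))
nn.train(est, split, "soleus")

x = mg.stack_features(split.test)
y = mg.stack_targets(split.test, "soleus")
pred = est.predict(x)
r = np.mean([mg.pearson_r(a, p) for a, p in zip(y, pred)])
nr = np.mean([mg.nrmse(a, p) for a, p in zip(y, pred)])
print(f"test r = {r:.1f}%, nRMSE = {nr:.1f}%")
# test r = 98.8%, nRMSE = 5.1%
```

Numbers vary slightly with BLAS/CPU but are reproducible for a fixed
environment and seed.

## Package layout

| module | contents |
| --- | --- |
| `myogait.signal_processing` | band-pass / rectify / low-pass envelope chain, median filter, invertible min–max normalization, power spectrum |
| `myogait.segmentation` | heel-strike stride segmentation, 101-point time normalization, time-domain reconstruction |
| `myogait.synthetic` | nine-muscle synthetic gait generator with IMU coupling and a decoupled negative-control mode |
| `myogait.datasets` | per-cycle samples, 80:15:5 split, subject holdout |
| `myogait.nn` | numpy FNN and LSTM regressors (Adam, dropout, early stopping) |
| `myogait.evaluation` | nRMSE, Pearson r, ΔTp, ΔEp; mean ± SD report tables |
| `myogait.io` | trial/event file formats, HDF5 cycle container, split manifest |
| `myogait.pipeline`, `myogait.cli` | resumable stage runner and the `myogait` command |
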