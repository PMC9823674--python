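# Methods

This document describes the signal model, the estimation pipeline, the
synthetic data generator, and the numerical choices made in `myogait`.
It is the reference for *why* the defaults are what they are; the README
covers *how* to run things.

## 1. Problem statement

Surface electromyography (EMG) measures muscle electrical activity but is
impractical to wear outside the laboratory. Inertial measurement units
(IMUs) are cheap and wearable. `myogait` estimates the *activation
envelope* of nine lower-extremity muscles over the gait cycle from the
signals of four body-worn IMUs (trunk, thigh, shank, foot; 3-axis
accelerometer and 3-axis gyroscope each, 24 channels total).

The estimation target is not the raw EMG but its smoothed, per-cycle,
amplitude-normalized envelope: a 101-point curve over 0–100 % of one gait
cycle (heel strike to next ipsilateral heel strike). One regression model
is fitted per muscle; its input is the 101×24 block of identically
normalized IMU channels for the same cycle.

## 2. EMG conditioning chain

Raw EMG is reduced to an envelope by the standard chain:

1. **Band-pass filter**, Butterworth, 20–400 Hz, order 4, applied
   forward–backward (`scipy.signal.sosfiltfilt`) for zero phase lag. The
   band retains the surface-EMG signal content while removing motion
   artifact (< 20 Hz) and high-frequency noise. Zero-phase filtering
   matters because peak *timing* is an evaluation metric; a causal filter
   would bias every peak late. The forward–backward pass squares the
   magnitude response, which the tests account for when checking
   attenuation against the analytic Butterworth curve.
2. **Full-wave rectification** (absolute value).
3. **Low-pass filter**, Butterworth, 8 Hz cutoff, order 4, zero-phase —
   the linear-envelope smoother. Filtfilt ringing can produce slightly
   negative values around sharp bursts; these are clipped to 0 because an
   envelope is nonnegative by definition.

Sampling rates are inferred from the file's time column; the band-pass
requires `fs ≥ 2 × band_high_hz` and fails with the required rate
otherwise.

## 3. Segmentation and normalization

* **Gait cycle**: the half-open interval `[strike_k, strike_{k+1})`.
  Sample indices are `ceil(t · fs)` at both ends so adjacent cycles never
  share a sample. Strides outside 0.4–2.5 s are flagged implausible and
  excluded from model data (they usually indicate missed or spurious
  events).
* **Time normalization**: linear interpolation of each stride onto a
  fixed 101-point grid (0, 1, …, 100 % of the cycle). Endpoints map
  exactly; the interpolation error is the usual `O(dx²)` bound, which the
  tests verify on a sine.
* **Median filter** (kernel 5, reflected edges) removes residual
  single-sample spikes. It runs *before* amplitude normalization so the
  normalized curve attains exactly 0 and 1.
* **Min–max normalization** per cycle: `y' = (y − min) / (max − min)`.
  The (min, max) pair is stored with every cycle, making the mapping
  exactly invertible; constant cycles are flagged degenerate rather than
  divided by zero. The same normalization is applied to each IMU channel
  per cycle, so the model sees shape, not amplitude, on both sides.

**Reconstruction** inverts the chain: denormalize with the stored
parameters, then interpolate each 101-point cycle back onto the original
time grid between its two heel strikes, concatenating cycles into a
continuous signal covering `[first strike, last strike)`.

## 4. Models

Two per-muscle regressors map the 101×24 IMU block to the 101-point
envelope:

* **FNN** — the block flattened to a 2424-vector, dense hidden layers
  with tanh activations and inverted dropout between layers, and a
  101-unit sigmoid output (one unit per % of gait cycle; sigmoid because
  targets live in [0, 1]).
* **LSTM** — the block consumed as a 101-step sequence of 24-channel
  vectors through stacked LSTM layers (dropout between layers); the final
  step's hidden state feeds the same 101-unit sigmoid head.

Both minimize mean squared error with Adam and early-stop on validation
loss, restoring the best weights.

The networks are implemented directly in numpy with hand-written
gradients (backpropagation through time for the LSTM). This keeps the
package dependency-light, fully deterministic under a seed, and fast
enough on one CPU for the problem sizes here. Correctness is pinned by
finite-difference gradient checks (max relative error ~1e-6 in float64)
and closed-form parameter counts in the test suite. Implementation
notes:

* Gate layout `[input | forget | output | candidate]` keeps the three
  sigmoid gates contiguous, so each timestep needs one sigmoid over a
  `(batch, 3H)` slab and one tanh.
* Sigmoid is computed as `0.5·(1 + tanh(0.5x))`: `np.tanh` is SIMD-
  vectorized and measured ~15× faster here than the alternatives.
* Forget-gate biases are initialized to 1 so memory is retained early in
  training; all weights use Glorot-uniform initialization (suited to
  tanh/sigmoid units).
* Training runs in float32 (halves CPU time, ample precision for these
  regressions); the gradient-check tests subclass the estimators with
  float64.
* Input-to-hidden products for all timesteps are computed in one matmul
  before the recurrence; weight gradients are accumulated with
  `tensordot` after the backward loop.

Default training configuration (the `model:` block): 2 layers × 64
units, dropout 0.2, learning rate 3e-3, batch 128, up to 120 epochs,
patience 15. These are deliberately small networks: the synthetic
problem (~720 cycles) would overfit much larger networks (e.g. 4×256), and
the defaults train each muscle in well under two minutes on one CPU.
Both architecture and all hyperparameters are configurable.

## 5. Evaluation metrics

Per cycle, with `X` the actual and `Y` the predicted 101-point envelope:

* **nRMSE** = RMSE(X, Y) / (max X − min X) × 100. Undefined (NaN) when
  the actual cycle is constant.
* **r** = Pearson correlation × 100. Undefined when either signal has
  zero variance.
* **ΔTp** = (actual peak time − predicted peak time), in % of gait
  cycle, signed, no circular wrapping. Peak ties resolve to the earliest
  index.
* **ΔEp** = |Xp − Yp| / Xp × 100, the relative peak-amplitude error.
  Undefined when the actual peak is zero.

Aggregation over a group of cycles reports mean ± sample SD (ddof 1) per
muscle; NaN cycles are excluded per metric with the exclusion count
reported, so included + excluded always equals the group size. ΔTp is
aggregated on absolute values (a symmetric timing error should not
average to zero); the signed mean is also reported to expose systematic
early/late bias.

## 6. Synthetic data generator

No EMG/IMU dataset ships with the package; the generator produces a
walking study whose structure matches what the pipeline expects, with
known ground truth so every stage can be tested against an oracle.

**What it emulates**

* Nine muscles, each a sum of one or two Gaussian bursts on the
  *circular* gait-phase axis (bursts near 100 % wrap into early stance).
  Burst timing follows standard gait-EMG phenomenology: plantar flexors
  peaking in terminal stance (soleus 44 %, gastrocnemius 42 %), tibialis
  anterior bursting at 70 % and again at terminal swing (97 %, wrapping),
  vasti and gluteus medius in loading response, hamstrings near 90 % with
  a stance-phase component around 30 % that grows in slow walking, and
  rectus femoris around 50 % with strong speed dependence plus 50 %
  crosstalk from vastus lateralis (modelling surface-electrode pickup).
* Three walking speeds (slow/normal/fast; mean stride periods
  1.25/1.10/0.95 s) cycled across trials, with per-subject period
  factors and stride-to-stride duration jitter.
* Per-subject variability: lognormal per-muscle and per-burst amplitude
  scalings, IMU gains/offsets, and subject-specific IMU waveform shapes.
* Raw EMG synthesized as the activation envelope amplitude-modulating a
  zero-mean 20–400 Hz carrier, plus low-frequency drift, a broadband
  noise floor and sparse impulsive artifacts — so the full conditioning
  chain is exercised from the raw end, and its recovery of the known
  envelope is testable.
* IMU channels are a subject-specific low-order Fourier series over gait
  phase **plus a linear mixture of the realized muscle activations and
  their derivatives**, plus sensor noise. The mixture makes the
  IMU → envelope map deterministic up to noise, so the learning problem
  is solvable by construction — verified in the tests by a linear ridge
  probe before any neural network enters.

**What it does not emulate**: electromechanical delay, nonstationary
fatigue effects, soft-tissue artifact spectra, turning/ramp/stair gait,
or the true biomechanical transfer from muscle force to segment
kinematics (the activation–IMU coupling is a generic linear mixture, not
a musculoskeletal model).

**Default problem size**: 4 subjects × 3 trials × 60 strides = 720 gait
cycles. This is a deliberate package-level choice: large enough that an
80:15:5 split leaves a meaningful test group and the networks clearly
beat a mean-shape baseline, small enough that the full study generates
in seconds and trains in minutes on one CPU.

**Determinism**: all randomness flows from one integer seed. Per-subject
substreams are derived as `default_rng([seed, crc32(subject_id)])`, so
studies are reproducible byte-for-byte across runs and platforms and
adding subjects does not perturb existing ones.

### Low-noise condition

Some properties (e.g. "the LSTM reaches nRMSE ≤ 10 % for every muscle")
are asserted under a *low-noise* configuration, defined once as:

```
imu_noise_sd = 0.005   emg_noise_sd = 0.005
burst_amp_jitter_sd = 0.05   burst_center_jitter_pct = 0.3
```

i.e. every stochastic disturbance reduced, with all structural parameters
(muscle set, coupling, speeds, subject variability) unchanged. Under
default noise the per-stride amplitude jitter places an irreducible floor
on nRMSE for the bimodal muscles (rectus femoris, hamstrings) of roughly
10–13 %, with correlations still ≥ 90; the low-noise condition isolates
what the estimator itself can achieve.

### Negative control

With `coupling_gain = 0` the generator removes the activation mixture
from the IMU channels **and** decouples burst timing from the gait cycle
(burst centers drawn uniformly per stride). Both are required for a
meaningful control: with zero coupling but phase-locked bursts, every
cycle's envelope is nearly the same curve, and any model that predicts
the mean shape scores r ≈ 0.9 without using the inputs at all —
information reaches the target through the shared phase convention, not
through leakage. Decoupling the timing makes the target genuinely
unpredictable from the IMU data, so held-out correlation near zero is
the correct expectation, and any residual skill would indicate leakage
through preprocessing, normalization, or the split.

## 7. Pipeline and reproducibility

`run-all` executes simulate → preprocess → split → train → predict →
evaluate → reconstruct against one run directory. Every stage records a
fingerprint (hash of its effective configuration plus upstream
fingerprints); a rerun skips stages whose outputs exist with unchanged
fingerprints, so interrupted runs resume per stage and changed configs
invalidate exactly the affected stages. The effective configuration,
library versions and seed are logged into the run directory.

The split is 80:15:5 (train:validation:test) over randomized gait
cycles, with validation/test sizes floored and the remainder going to
train. Splitting by whole trials is available (`split.by: trial`), and
one whole subject is held out as *unseen-subject* data
(`split.unseen_subject`, default: drawn from the seed) to measure
generalization to a person the model never saw. Reported tables include
both the test group and the unseen subject.

## 8. Limitations

* The generator's activation–IMU coupling is linear and study-wide; real
  kinematics are nonlinear and subject-specific. Absolute metric values
  on synthetic data say nothing about performance on real recordings.
* Per-cycle min–max normalization discards amplitude information by
  design; models estimate envelope *shape*. Reconstruction to physical
  units requires the stored per-cycle parameters, which for predicted
  cycles come from the measured EMG — on a truly EMG-free deployment the
  amplitude scale would need a separate calibration.
* Heel-strike events are taken as given (the generator knows them
  exactly); no event-detection algorithm is included.
* Only level walking at three speed classes is modelled.
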