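# Methods

This note documents the models, parameter choices, and numerical
conventions behind `crsdetect`, and what the synthetic evaluation does and
does not establish.

## Problem setting

A wrist-worn watch streams 3-axis total acceleration (m/s², gravity
inclusive) and a 3-axis gyroscope signal at ~20 Hz to a phone, which must
decide in real time whether the wearer is smoking. The hard part is not
detecting hand-to-mouth motion but *rejecting* the many everyday gestures
with nearly identical kinematics (eating, drinking, yawning, adjusting
glasses, …). The CRS classifier treats 15 such confounders as explicit
negative classes during training.

## Synthetic gesture simulator

No wrist-IMU dataset ships with the package; the simulator in
`crsdetect.gestures` emulates the collection protocol instead: 16
activities (15 confounders + smoking), up to 3 postures (seated, standing,
walking), 5 s per trial at 20 Hz, a default cohort of 21 participants
(the usable cohort size after exclusions in studies of this design), with
log-normal per-participant amplitude (σ=0.12) and tempo (σ=0.10)
multipliers and log-normal scaling of a cohort-level accelerometer noise SD
(default 0.3 m/s², a realistic consumer-IMU figure; "low-noise" runs use
0.05).

Each gesture is a **phase sequence**: per cycle, raise → plateau → lower →
rest, repeated `cycle_count` times per trial, with per-class parameters in
the `GESTURE_CLASSES` template table (cycle-count range, amplitude,
pitch/roll/yaw ranges, plateau fraction, plateau oscillation frequency,
mouth-proximality). The signal model is:

- **Gravity**: the 9.81 m/s² vector rotated through the sensor frame by the
  wrist pitch/roll trajectory; its magnitude is exactly 9.81, so per-trial
  mean |accel| stays in a physically plausible 8.5–11.5 m/s² band.
- **Linear acceleration**: second derivatives of the hand trajectory,
  peak-normalized to ±2.2·amplitude m/s² (raw curvature of a 20 Hz-sampled
  ramp would otherwise spike unphysically).
- **Gait**: walking superimposes a ~1.9 Hz vertical bounce (1.2 m/s²) and
  arm-swing component; standing adds a small 0.3 Hz sway.
- **Gyroscope**: by default an angular-rate-like signal (smoothed
  derivative of the orientation angles); an `orientation` mode emits the
  angles themselves, since deployed watches differ in which convention the
  "gyroscope" stream uses.
- **Phases are annotated per sample** (`rest/raise/hold/active/lower`) so
  tests can reason about gesture structure (e.g. smoking has ≥2
  raise–lower cycles; waving has no mouth-proximal hold) without
  re-deriving kinematics.

Timestamps are exactly 20 Hz by default; a jitter flag perturbs them by
±20% of a sample period to emulate "approximately 20 Hz" clocks.

**What the simulator does not emulate**: biomechanically validated human
motion, sensor bias/drift and axis miscalibration, intra-trial pauses,
gesture co-articulation (smoking while walking and talking), or
device-specific sampling irregularities. Consequently, passing the
synthetic learning tests shows the pipeline is *correct and trainable*, not
that the reported operating points transfer to human data — synthetic
classes are cleanly separable by design (a nearest-centroid classifier on
kinematic summary features reaches ≥95% smoking-vs-rest accuracy at zero
noise, which guarantees the CNN targets are achievable).

## Gravity separation

A first-order recursive low-pass filter per axis:
`g_t = α·g_{t−1} + (1−α)·a_t`, `linear_t = a_t − g_t`, with α = 0.8 — the
deployed constant, exposed in configuration. Closed form under constant
input from `g_0 = 0`: `g_t = (1 − αᵗ)·a`, so initialization transients
decay as αᵗ (0.8¹⁰⁰ ≈ 2×10⁻¹⁰). The filter state is initialized to the
first raw sample by default (the stream then starts at zero linear
acceleration instead of a g-sized transient contaminating the first
window); a `zeros` mode matches the textbook recursion. State resets at
recording boundaries — trials are independent — and runs continuously
within a stream. Gyro channels are never filtered.

## Classifier

Architecture (input 200 time points × 6 channels, treated as a
single-channel 2D grid so kernels span time and sensor axes jointly):

| stage | shape out | parameters |
|---|---|---|
| conv 8 @ 5×5, leaky ReLU | 200×6×8 | 208 |
| conv 16 @ 3×3, leaky ReLU | 200×6×16 | 1 168 |
| maxpool 2×1 | 100×6×16 | — |
| conv 32 @ 3×3, leaky ReLU | 100×6×32 | 4 640 |
| maxpool 2×1 | 50×6×32 | — |
| dense 1024, leaky ReLU | 1024 | 9 831 424 |
| dropout 0.5 | 1024 | — |
| dense K, softmax | K | 1024·K + K |

Total 9 839 490 parameters for K=2; the 2- and 16-class variants share
everything but the output width. Design choices where the architecture
description left freedom, documented so parameter counts are reproducible:

- **"Same" zero padding on all convolutions** — a 5×5 kernel on a 6-wide
  sensor axis would otherwise nearly exhaust it.
- **Pool placement** after the second and third convolutions (pools are
  "interspersed"; this placement preserves width for the 5×5-then-3×3
  kernel sequence).
- **Leaky-ReLU slope 0.01**; also applied to the 1024-unit dense layer
  (without a nonlinearity there the two dense layers would collapse into
  one linear map).
- **Optimizer Adam** at the stated learning rate 0.001 (β₁=0.9, β₂=0.999);
  training uses categorical cross-entropy, batch 32, up to 100 epochs.
- **Normalization**: per-channel z-scoring with statistics fit on training
  data only, stored in the checkpoint and applied at inference.
- **Decision rule**: argmax (0.5 threshold for 2 classes); ties break to
  the lowest class index; ROC analysis sweeps the smoking-class
  probability.

The layers (stride-1 same-padded conv2d via im2col, 2×1 max pooling, dense,
inverted dropout, fused softmax/cross-entropy, Adam) are implemented in
numpy (`crsdetect.nn`), in float32, with weight init, shuffling and dropout
all drawn from seeded generators, so training is exactly reproducible.
Gradient correctness is pinned by central-difference checks and an
overfit-capacity test (32 memorized windows reach near-zero loss well
within 100 epochs).

### Windows

A 5 s trial at 20 Hz yields 100 samples; the model consumes 200. Trials are
tiled (default 2 repeats, configurable) to fill one 200×6 window of
[linear accel x,y,z | gyro x,y,z]. One window per trial keeps trial counts
and window counts aligned with the protocol arithmetic.

## Streaming detection

Two queues (accelerometer, gyroscope) accumulate processed samples,
synchronized by arrival index; when both hold 200 entries the window is
classified and the buffers drain entirely (tumbling windows — matching a
queue that "holds values until they accumulate 200 entries"; a sliding
stride exists but is off by default). A smoking classification at
window-completion time `t` emits a notification iff none was emitted in
`(t − 450 s, t]`; otherwise the detection is logged as `suppressed`, so the
event stream remains auditable and the cooldown window is *not* restarted
by suppressed detections. The cooldown (450 s ≈ one cigarette) is measured
on the stream's wall clock from notification emission.

The link is a five-phase state machine (`idle → greeted → acknowledged →
streaming → disconnected`): greeting and acknowledgment form the handshake,
the first heartbeat starts streaming, heartbeats are expected every 3 s,
and 6 s of heartbeat silence drops the link at exactly
`last_heartbeat + 6 s`. Samples arriving while the link is not streaming
are dropped and counted, giving the conservation identity
`windows·200 + buffered + dropped = generated` checked by tests. Cloud
upload is represented only by local file writers; no transport is real.

## Evaluation battery

- **Splits**: 60/20/20 train/test/evaluation by nearest-integer rounding
  with the training subset absorbing the remainder — the rule that maps
  n = 1054 to exactly 632/211/211. Stratified splits apply the same rule
  per class (proportions preserved within ±1 item per class).
- **Rates**: TPR, FPR, precision, recall, F1 from the standard binary
  cells; one-vs-rest reduction for K>2 with smoking designated positive *by
  name*. Zero-denominator convention: undefined precision/recall/F1 → 0.
- **ROC/AUC**: thresholds at every unique score (plus +∞), one vertex per
  tied group, trapezoidal area. This equals the Mann-Whitney
  pairwise-concordance probability with ties counted ½; tests assert
  agreement to 10⁻¹⁰ against the exhaustive oracle.
- **LOSO**: one fold per participant, that participant absent from
  training, window-level accuracy, sample SD (ddof=1), outliers = strictly
  beyond mean ± 1 SD.
- **Confound attribution** (16-class): per confounder, the row-normalized
  rate it is predicted as smoking and the rate smoking is predicted as it.

## Problem sizes and seeds

The learning checks train the full 9.8M-parameter network in numpy, so the
suite uses deliberately compact cohorts: held-out F1 is measured on the
21-participant low-noise cohort (1008 windows, 25 epochs), and LOSO on a
6-participant cohort (288 windows, 20 epochs per fold). All seeds are fixed
in tests; `scripts/acceptance.py` derives every stream of randomness from
its `--seed` argument.

## Known limitations

- Synthetic data only; headline numbers from human-cohort studies of this
  pipeline (e.g. F1 ≈ 97.5%, AUC ≈ 0.99, LOSO ≈ 86%) are benchmarks on
  data this package cannot access, and the synthetic analogues here are
  intentionally easier.
- The numpy CNN is single-threaded and CPU-bound; it is a reference
  implementation, not a production trainer.
- The 16-class variant is architecturally supported and tested for
  shape/contract correctness, but the bundled evaluations train the
  2-class model (16-class training at these cohort sizes adds cost without
  changing what the tests establish).
- The link simulator models protocol logic, not radio behavior (no loss,
  reordering, or latency).
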