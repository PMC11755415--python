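# Methods

## Problem setting

Cuffless blood-pressure (BP) estimation infers systolic (SBP) and diastolic
(DBP) arterial pressure, in mmHg, from non-invasive optical and electrical
signals: the photoplethysmogram (PPG), whose morphology is coupled to the
arterial pressure wave, and the electrocardiogram (ECG), whose R-peaks mark
beats and whose lag to the peripheral pulse (pulse transit time, PTT)
correlates inversely with pressure. `pulseguard` implements a family of
sequence-regression networks for this task, a distance-based anomaly
detector for monitoring streams, analytic cost accounting, and descriptive
heart-rate analytics — all exercisable offline on a bundled synthetic
signal simulator.

## The synthetic cardiovascular simulator

Real waveform corpora of this kind are access-controlled ICU databases, so
the package ships a generator whose records have *known* per-beat SBP/DBP
ground truth.

Per subject, a heart rate is drawn uniformly (default 55–95 bpm) and the
record is a concatenation of fixed-length beats. Each beat's arterial
pressure (ABP) is a template — a systolic Gaussian lobe plus a dicrotic
bump on a diastolic baseline — rescaled per beat so the sampled extrema
equal that beat's drawn SBP (peak) and DBP (trough). Subject-level BP is
drawn uniformly from the configured ranges (defaults 100–160 / 60–90 mmHg);
within a record it wanders slowly (a smoothed random walk, sd ≈ 6% of the
range width) with small beat-to-beat jitter (2%), mimicking minute-scale
physiological BP variability.

The **coupling dial** (`coupling_strength` ∈ [0, 1]) controls how strongly
waveform *morphology* encodes the BP level:

- higher SBP → narrower systolic lobe (phase width 0.17 → 0.05),
- higher DBP → taller dicrotic bump (relative amplitude 0.10 → 0.60),
- higher BP overall → later dicrotic bump (phase 0.45 → 0.70),
- higher systolic (and mean) pressure → shorter R-peak-to-pulse lag
  (280 ms → 140 ms), the inverse PTT-BP cue carried by the ECG channel.

At coupling 0 all of these are frozen, so the normalized waveforms carry no
BP information — the floor against which learnability claims are tested. At
coupling 1 the encoding is a clean monotone map. PPG is the ABP smoothed
with a 50 ms moving average, min-max normalized per record, plus Gaussian
noise (`noise_sd`, default 0.05 of the unit amplitude); ECG is a train of
narrow Gaussian R-peaks plus the same noise. Sampling rate defaults to
125 Hz, the usual convention for ICU waveform archives.

Deliberate simplifications: no validated hemodynamic model, no arrhythmia,
no motion artifacts, no sensor drift. Morphology couplings are chosen to be
smooth and monotone — which makes the mapping *learnable by design*.
Passing tests therefore demonstrate that the pipeline can extract a
morphology-encoded BP signal at realistic noise levels; they do not
demonstrate clinical-grade accuracy on real patients.

Determinism: each record depends only on `(seed, subject_index)` through an
independent seed-sequence stream, so cohorts are reproducible and
order-independent.

Windowing (`make_dataset`) cuts fixed-length windows on a stride grid —
window starts fall at arbitrary cardiac phases, as they would for a
free-running wearable. Each window carries the beats fully contained in it;
a window's SBP/DBP target is the mean of those beats' labels. Beat
intervals are half-open `[onset_k, onset_{k+1})` and the trailing partial
beat is dropped.

## Network families

Five families are assembled from shared primitives (cross-correlation
"convolution", ReLU, 2×-max-pooling, the classical LSTM cell, residual skip
connections, softmax), each with a PPG-only or PPG+ECG input configuration
and one of three heads: direct SBP/DBP regression (two outputs, de-normalized
from z-scores with training-set statistics), entire-waveform regression
(one output per input sample), or a softmax hypertension-stage classifier.

- **fully_connected** — flattened window through `depth` ReLU dense layers.
- **lstm** — the window, decimated by average pooling (factor 5 by
  default), fed to a single LSTM; the final hidden state is the feature.
- **wavenet** — `depth` dilated *causal* 1-D convolutions with dilation
  doubling per layer (1, 2, 4, …) and residual sums, then global average
  pooling. The original gated tanh/σ units are deliberately omitted; the
  receptive field still grows as ~2^depth · kernel.
- **wavenet_lstm** — the dilated stack followed by an LSTM.
- **resnet_lstm** — the hybrid: five convolutional blocks holding
  (3, 3, 2, 2, 2) same-padded convolutions of kernel 3 with ReLU and one
  residual skip per block, each block closed by a 2-wide max-pool and a
  25% dropout layer (12 convolutions, 5 pools in total), then one LSTM
  layer, one fully connected layer, and the head. In the first block the
  skip is taken after the first convolution so channel widths match
  without an extra projection layer; this keeps the stated 12-convolution
  count exact.

All models are one-dimensional. The stage-classifier head sits on the same
1-D encoder; a separate 2-D image pipeline was considered and dropped
because the BP task is signal regression and nothing downstream needs it
(the 2-D convolution/pooling primitives themselves exist and are tested).

LSTM detail: the candidate state has its own parameters `W_c, b_c`. A
`tie_candidate_to_input_gate` flag reproduces the non-standard variant in
which the candidate reuses the input gate's parameters — some descriptions
print the equations that way, almost certainly a typo, but both behaviours
are available and tested.

Weights are He-style uniform, scaled by fan-in, fully seeded. The training
engine is an in-package reverse-mode autodiff on numpy arrays (single
precision, the standard choice for network training); the primitive
forward semantics are pinned separately in double precision against
brute-force oracles.

## Training and evaluation

Loss is MSE on z-scored targets (targets are re-scaled to mmHg at
prediction time). Adam with per-epoch exponential learning-rate decay;
a 10% window-level validation split drives early stopping (the best
validation parameters are restored). All randomness — initialization,
shuffling, dropout, splits — derives from the configured seed. Exact
bit-determinism is guaranteed only per platform; tests therefore assert
thresholds, not byte equality, for learned quantities.

**Leave-one-subject-out (LOO)**: one fold per subject, trained on the
rest. *Direct* mode scores the two head outputs against per-window SBP/DBP
labels; *entire* mode scores the predicted ABP waveform (MAE/RMSE) and
additionally derives per-beat SBP/DBP from the predicted waveform via the
per-beat max/min extractor before scoring. Waveform-level columns are
reported as absent in direct mode. Aggregates are sample-count-weighted
means of fold metrics, so RMSE ≥ MAE survives aggregation.

### The desk-scale benchmark

The canonical study (module `pulseguard.benchmark`): 12 subjects, 60 s
each, 125 Hz, coupling 1, noise 0.05; 2.5 s windows on a 2.5 s stride
(24 windows per subject); hybrid ResNet+LSTM at reduced width — 6
convolutional channels, hidden size 16, dropout 0.05 instead of 0.25 —
trained 80 epochs (lr 3e-3, decay 0.97/epoch, batch 32). The reduced
width and the lighter dropout are deliberate desk-scale choices: at ~2,500
parameters the full 25% per-block dropout swamps the signal, and the small
widths keep a 12-fold LOO pass in the minutes range on one CPU. Reference
predictors are the least-squares linear baseline on flattened windows
(minimum-norm solution when rank-deficient) and the training-mean
predictor. Because window starts are phase-random and the morphology cues
are partly positional, the convolutional hybrid outperforms the linear
baseline by a wide margin here — mirroring the *direction*, not the
magnitude, of full-scale results on real ICU data, which this benchmark
does not attempt to reproduce.

The ECG-channel comparison (PPG vs PPG+ECG) uses a held-out 10%
validation split after full-cohort training rather than another full LOO
pass: the question is whether the extra channel hurts, and the cheaper
estimate answers it across seeds within the compute budget.

## Complexity accounting

Costs are counted as multiply-accumulates with the convention
1 MAC = 1 FLOP. The order-level estimator assigns `L · V_dim²` to the
fully connected and LSTM families and `L · V_dim² · k_size` to the
convolutional families; activation and pooling costs are excluded at the
order level (available behind a flag in the exact counter). Because width
enters quadratically, doubling the input dimensionality with
width-scaling enabled (`scale_width_with_channels`) multiplies cost by
~4 — the mechanism behind the ≈4× PPG+ECG vs PPG cost pattern. Absolute
published FLOPs figures are not reproducible without the (unstated)
layer sizes, so only orders and ratios are asserted.

## Model-of-normality anomaly detection

A MoN is the arithmetic mean of N normal feature embeddings; test samples
score by Euclidean distance to it and are flagged when the score strictly
exceeds the working-point threshold (ties are normal). The extractor is
pluggable; the bundled default is a seeded two-layer random-projection
encoder (`tanh(W₂ relu(W₁x))`, never trained), so the detector runs
without pretrained weights.

The six threshold rules operate on two calibration score vectors: K1 from
*max-pooled* and K2 from *mean-pooled* embeddings of a held-out normal
calibration split — the only reading that gives both vectors a concrete
origin; the pooling pair is exposed as a strategy. `std` is the population
standard deviation. The MoN-building normals and the calibration normals
are disjoint splits (first half / second half), so calibration scores are
honest out-of-sample distances. One MoN is built per data class; dispatch
scores against the designated class's MoN only.

## Wearable heart-rate analytics

Zone minutes attribute each inter-sample interval to the zone of its
leading sample (exactly conserving total duration, robust to irregular
sampling). Default zone boundaries are the conventional
percentage-of-maximum-heart-rate bands (50 / 70 / 85% of a default 190
bpm maximum) — device vendors do not publish theirs — and are fully
overridable. Quantiles use linear interpolation (type 7); outliers are
Tukey fences at 1.5·IQR. Correlation matrices are Pearson; a constant
channel raises an error naming the channel rather than emitting NaN.

## Numerical and design notes

- Convolution is implemented literally as cross-correlation (the
  deep-learning convention); no kernel flipping.
- Softmax subtracts the maximum before exponentiation.
- The residual mapping is the canonical `H(x) = F(x) + x`, with an
  optional projection when shapes differ.
- The 12 convolutions of the hybrid are allocated (3, 3, 2, 2, 2) across
  the five blocks; the split is otherwise underdetermined.
- `extract_sbp_dbp` on the simulator's own noiseless ABP reproduces the
  drawn labels exactly (the template is normalized per sampled beat), so
  label consistency is testable to well under 0.5 mmHg.
- WFDB-format input is not supported: no WFDB reader dependency is
  available in this distribution, and nothing in the package requires
  those records; CSV and HDF5 record IO are provided instead.

## Known limitations

- The simulator's morphology–BP coupling is smooth, monotone and
  noise-free beyond additive Gaussian noise; real PPG/BP coupling is
  weaker, subject-specific and confounded. Desk-scale rankings should not
  be read as clinical performance.
- Single-precision training puts a ~1e-3 relative floor on reproducibility
  across BLAS builds; seeds fix results only per platform.
- The LSTM family consumes decimated input by default; very long windows
  at full rate are out of its intended use here.
- `stage_classifier` training expects integer class labels supplied by the
  caller (e.g. guideline stages of the window labels); no class-imbalance
  handling is built in.
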