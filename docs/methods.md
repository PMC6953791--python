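# Methods

## Problem

Bedside monitors in intensive care trigger alarms for five life-threatening
arrhythmias — asystole (ASY), extreme bradycardia (EBR), extreme tachycardia
(ETC), ventricular tachycardia (VTA) and ventricular flutter/fibrillation
(VFB) — and the large majority of those alarms are false, caused by noise,
motion and sensor artifacts rather than by the heart.  `falarm` classifies a
triggered alarm as *true* or *false* from the waveforms recorded immediately
before the alarm, in the real-time setting: no sample at or after the alarm
onset is ever used.  Three modalities are supported: ECG lead II, arterial
blood pressure (ABP) and the photoplethysmogram (PPG), all at 250 Hz, the
layout of the PhysioNet/CinC Challenge 2015 records.

## Model

Each modality has its own feature-extraction network.  The pre-alarm
analysis window (default 16 s) is min-max normalized to [0, 1] *as a whole*
(so inter-segment amplitude structure such as a flatline survives; no
filtering or denoising is applied anywhere) and cut into 200-sample windows
with 25 % overlap (stride 150), giving a sequence of T = 26 segments.  Per
segment t:

1. Two 1-D convolutions (32 then 64 filters, kernel 2, stride 1, ReLU) with
   an intermediate max-pool (region 2, stride 2) produce 64 feature maps of
   length 98, which an adaptive pool over contiguous near-equal bins reduces
   to L slice vectors C_{t,1..L} in R^64 (default L = 10).
2. Additive attention scores each slice against the previous top-layer LSTM
   hidden state, `score_i = v . tanh(W_h h_{t-1} + W_C C_{t,i})`; a softmax
   over the L scores gives weights alpha_{t,i} and the context
   c_t = sum_i alpha_{t,i} C_{t,i}.
3. A two-layer LSTM (256 units each, zero initial state) consumes c_t; the
   top hidden state conditions the next step's attention.

After the last segment, a fully connected layer of 256 ReLU units maps h_T
to the modality embedding; a softmax head produces the two class
probabilities.  For multimodal classification the three embeddings (softmax
heads stripped) are averaged elementwise and passed through FC-256 + ReLU,
dropout p = 0.5 (training only), and a 2-class softmax.

### Loss

Let the per-sample error be the mean over the two softmax units of the
squared difference to the one-hot label (with two units, mean versus sum is
a constant factor 2 — the mean is fixed here for reproducibility), and
l(g) the mean of that error over the samples of class g.  The losses are

    L_MSE  = mean over all samples,
    L_MFE  = sum_g l(g),           (mean false error)
    L_MSFE = sum_g l(g)^2,         (mean squared false error)

so MFE/MSFE weight each class equally no matter how rare it is; a mini-batch
missing one class contributes only the present class's term.  The training
objective adds an L2 penalty beta * sum(theta^2) over trainable parameters,
beta = 0.001.  MFE is the default.

### Training

Two steps.  Step 1 trains each modality network end to end on the true/false
labels (RMSProp, learning rate 0.001, decay 0.9, epsilon 1e-8, mini-batches
of 10, up to 100 epochs by default).  Step 2 strips each softmax head,
freezes the backbones (frozen networks are never touched by the optimizer —
verified bitwise in the tests) and trains only the fusion head with the same
hyperparameters.  Experiments run stratified k-fold cross-validation
(default k = 10; k = 5 conventional for per-alarm-type runs) with both steps
repeated inside every fold; held-out predictions are pooled across folds and
scored once, with per-fold panels retained.  Optional early stopping on a
training-loss plateau (patience 10, min-delta 1e-4) is off by default.

All arithmetic is NumPy with hand-derived backpropagation, checked against
central finite differences for every parameter tensor and every loss in the
test suite.  Every random draw (initialization, batch order, dropout, fold
shuffling, data generation) comes from a generator derived from the
experiment seed, so any run is bit-reproducible.

### Numerical and design choices

Points the architecture sketch leaves open were resolved as follows:

- **Slice pooling.** The convolution stack yields 98 temporal positions;
  pooling them into L slices by *averaging* shrinks the (non-negative,
  post-ReLU) features by roughly the bin width, which measurably starved the
  upper layers of signal: at desk scale (tens of epochs) the readout never
  left chance.  Bins are therefore *sum*-pooled by default
  (`ModalConfig.slice_pool = "avg"` restores plain averaging), and the
  default L is 10 — narrower bins keep single-QRS events visible against the
  baseline energy of a bin.
- **Initialization.** Glorot-style uniform throughout, with gain sqrt(2) on
  ReLU layers (both convolutions, FC, output) and orthogonal recurrent
  blocks per LSTM gate — the standard recipe for trainable LSTMs.  Forget
  gate bias starts at 1.  The attention parameters use plain Glorot.
- **Attention scorer.** The slice-to-scalar projection is the learned vector
  v (additive attention) with width A = 64.  With L = 1 the unit reduces to
  the identity on its single slice.  Disabling attention
  (`attention_enabled=False`) substitutes exactly uniform weights 1/L, for
  ablations.
- **Classification state.** The final step's top hidden state h_T feeds the
  FC layer; no pooling over time.
- **Ties and degenerates.** Predicted label is the argmax with ties resolved
  to *true alarm* (missing a true alarm costs five-fold in the challenge
  score); min-max normalization of a constant signal returns zeros; metric
  ratios with zero denominator are reported as NaN with a flag, never
  silently as 0; trailing samples that do not fill a 200-sample window are
  dropped.
- **Analysis window.** The pre-alarm window length W is configurable
  (default 16 s = 4000 samples -> 26 segments), long enough to contain the
  >= 4 s events that define ASY and VFB with normal-rhythm context around
  them.

## Synthetic data

The generator emulates the statistical structure of the five alarm types so
the full pipeline is testable without any download.  A latent beat schedule
realises the alarm definition constructively — bradycardia below 40 bpm,
17+ consecutive beats above 140 bpm, >= 5 ventricular beats above 100 bpm, a
>4 s silent gap, a >= 4 s oscillatory interval — and is stored on the record
as exact ground truth; definitions are *never* recovered by beat detection
from the rendered signal.  False-alarm records have a normal rhythm
(75-95 bpm) with an artifact process (broadband noise burst, electrode-pop
square transients, or a railed flatline dropout) injected near the record
end into the ECG — the channel the arrhythmia detector watches, without
which no false alarm would have been raised — and, half the time, one
pulsatile channel as well, so the corrupted channels mimic an alarm while
at least one channel stays clean.  Rendering uses Gaussian-bump QRS trains
(wide bumps for ventricular beats, a 4-6 Hz oscillation for VFB) and
raised-cosine ABP/PPG pulses with a dicrotic bump, plus sinusoidal baseline
wander and white noise, quantized to the 12-bit grid used by the record
writer so write -> read is lossless.

Generator defaults (heart-rate ranges, noise sigma 0.02, wander 0.04, burst
gain 5, square amplitude 3.5, transient artifact lengths of 1.5-3 s against
sustained >= 4 s true events) were calibrated once so that the task is
learnable by this architecture within tens of epochs yet not separable by a
trivial amplitude threshold, and are frozen.  What passing tests on this
generator shows is that the pipeline can extract rhythm and artifact
structure from multichannel waveforms under the stated protocol; it does
not certify performance on real ICU recordings, whose artifacts, lead
placements and rhythm variety are far richer.  An optional replication
harness (`falarm run-cv` pointed at a Challenge-2015 directory with an
answers CSV) runs the identical protocol on real records when they are
available locally.

## Problem sizes used in the checks

The acceptance checks run the full protocol at desk scale: the end-to-end
experiment uses 120 balanced records, single-modal ECG, 5-fold
cross-validation and 30 epochs; the imbalance ablation uses 200 records at
1:9 true:false over five seeds with 10 epochs and a stratified 70/30 split;
the freeze check uses 30 records and 3 epochs; determinism is verified by
re-running a complete 40-record experiment.  These sizes were chosen so the
whole suite completes on a single CPU in well under an hour while still
exercising every pipeline stage.

## Known limitations

- The waveform sketches are morphological cartoons; no ectopy outside VT
  runs, no atrial arrhythmias, no heart-rate drift within a record.
- Records are fixed at 250 Hz; resampling and physical-unit calibration are
  out of scope, as are rule-based QRS/SQI baselines.
- MFE/MSFE on a softmax have the usual flat spots of squared-error losses;
  with the stated optimizer and epoch budgets a minority of random
  initializations converge to a biased operating point (high sensitivity,
  lower specificity).  The cross-validation protocol averages over five
  independently initialized networks, which damps but does not eliminate
  this variance.
- The WFDB support covers exactly the Challenge-2015 layout (format-16 .dat
  or MATLAB v4 .mat, single frequency, gain/baseline calibration), not the
  full format family.
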