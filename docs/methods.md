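# Methods

## Problem and model

`sleepstager` classifies 30 s polysomnography epochs into the five AASM
sleep stages (W, N1, N2, N3, REM) from four raw 100 Hz channels: the two
bipolar EEG derivations Fpz–Cz and Pz–Oz, one horizontal EOG, and the
submental (chin) EMG. Each epoch is scored independently — the network sees
a `(4, 3000)` array and emits a 5-class posterior.

The network has three stages:

1. **Multi-scale convolutional feature extraction.** The four channels are
   grouped into three modalities (EEG with two input channels, EOG, EMG).
   Each modality passes through two parallel 1-D convolution branches:
   a *small-kernel* branch (kernel 50 samples = 0.5 s, stride 6, max-pool 8)
   tuned to transient activity such as sleep spindles, and a *large-kernel*
   branch (kernel 400 samples = 4 s, stride 50, max-pool 4) tuned to slow
   trends such as N3 delta waves. A branch is conv → batch norm → LeakyReLU
   (slope 0.01) → max pool → dropout (p = 0.5). With 3000-sample input the
   branches emit 61 and 13 time steps respectively
   (`floor((floor((3000−k)/s)+1)/p)`), concatenated along the time axis to
   74 steps of 64 features, small-kernel features first.
2. **Squeeze-and-excitation (SE) channel attention**, applied per modality
   after the branch concatenation: each of the 64 feature channels is gated
   by `s = sigmoid(W2 relu(W1 z))`, where `z` is the channel's global time
   average and the bottleneck width is 64/4 = 16 (reduction ratio r = 4, no
   biases). The three gated modality maps are then concatenated along the
   feature axis (192 features) and transposed to `(batch, 74, 192)`.
3. **BiLSTM + attention pooling + classifier.** A single-layer
   bidirectional LSTM (128 hidden units per direction) encodes the
   74-step sequence; softmax attention `α_t ∝ exp(vᵀ tanh(W_h h_t + b_h))`
   (attention width 128) pools the hidden states into one 256-dim context
   vector; dropout (p = 0.5) and a fully connected softmax layer produce the
   posterior. Training minimizes batch-mean cross-entropy computed from
   logits in log-sum-exp form. Inverse-frequency class weights
   `w_k = N/(K·N_k)` are available but **off by default**, matching the
   plain cross-entropy objective.

### Ablation variants

`build_variant(name)` produces, from the same configuration: `no_msconv`
(small-kernel branch only, 61 time steps), `eeg_only` (EOG/EMG paths removed,
64-wide features, LSTM resized), `no_se` (gating replaced by identity),
`no_lstm` (attention pooling applied directly to the 192-dim convolutional
sequence), and `no_attn` (context = last BiLSTM output step). `no_attn`
shares every parameter shape with the full model except the absent attention
parameters; `eeg_only`, `no_se`, and `no_lstm` are strictly smaller.

### Design choices where the architecture was open

Several hyperparameters are not pinned down by the architecture description
this implements; they are fixed once in `ModelConfig` and treated as
configuration, not claims: 64 filters per branch, strides/pools (6/8, 50/4)
chosen so the two branch lengths are of the same order (61 vs 13), SE
reduction 4, LSTM width 128, attention width 128, LeakyReLU slope 0.01,
one conv block per branch, and uniform fan-in initialization
U(±1/√fan_in) from a seeded generator. The two EEG channels share one
two-channel-input branch rather than two separate branches, so "EEG" is a
single modality in the fusion.

## Numerical engine

No deep-learning framework is used: the package carries its own tape-based
reverse-mode autodiff on numpy (`autodiff.py`) with exactly the primitives
the model needs (strided 1-D convolution via an `as_strided` im2col,
non-overlapping max pooling, LSTM unrolling with a shared-buffer time-slice
op, fused softmax cross-entropy). Every primitive is checked against
central-difference numerical gradients in float64 in the test suite, and the
whole LSTM is gradient-checked end to end. Forward/backward runs in float32;
scalar constants are coerced to the graph dtype so no silent float64
promotion occurs. The Adam optimizer uses the standard bias-corrected
moments (β₁ = 0.9, β₂ = 0.999, ε = 1e-8).

## Data pipeline

* **EDF ingestion** uses `mne` for reading (signals and EDF+ annotations).
  Channels are matched by case-insensitive substring against the Sleep-EDF
  label dialect ("EEG Fpz-Cz", "EEG Pz-Oz", "EOG horizontal",
  "EMG submental"); event-marker and temperature channels are ignored.
  All channels are brought to a common 100 Hz: upsampling (the public
  Sleep-EDF cassette files store the chin EMG at 1 Hz) is linear
  interpolation — the EMG only carries a slow tone envelope — and
  downsampling is polyphase and anti-aliased. A minimal 16-bit EDF/EDF+
  writer exists so synthetic fixtures can exercise the full ingestion path;
  round-trip error is bounded by (physical range)/2¹⁵ per channel.
* **Label mapping** follows the Sleep-EDF dialect of the R&K standard with
  stages 3 and 4 merged into N3; "Movement time" and unscored slots are
  excluded. Epoch length is the AASM-standard 30 s.
* **Wake trimming** keeps W epochs only within a margin (default 30 min)
  before sleep onset and after final offset. The margin is exposed as a
  flag because the literature's epoch counts for this dataset are consistent
  with the 30 min convention while the accompanying prose is ambiguous.
* **Normalization** is a per-recording, per-channel z-score (ε = 1e-8 guard
  maps constant channels to zeros). Raw EDF channels differ in physical
  scale by orders of magnitude; unnormalized fusion destabilizes training.

## Training protocol

Subject-disjoint k-fold cross-validation (default k = 5): subjects are
randomly partitioned into test folds differing by at most one subject, and
all of a subject's recordings travel together, so no individual contributes
to both sides of a fold (`check_no_leakage` audits this). Within each fold,
10% of training *epochs* are held out for early stopping — stratified by
class, because N1 is rare enough that an unstratified 10% holdout is
unstable. Training uses Adam at learning rate 0.001, batch size 64 (last
partial batch kept), a fresh shuffle per epoch from a per-fold derived seed,
at most 100 epochs, and stops when the validation loss has not improved for
5 consecutive epochs; the best-epoch parameters (including batch-norm
running statistics) are restored. A non-finite loss aborts with the batch
index. The holdout is epoch-level rather than subject-level — the literal
reading of "10% of the training samples" — and no learning-rate schedule is
applied beyond the initial rate.

## Synthetic study conditions

The generator (`synth.py`) exists so the whole system is trainable and
testable without the benchmark download. It emulates exactly the cues the
architecture targets, and nothing else:

* **Hypnograms** are first-order Markov chains. The default transition
  matrix is `P = d·I + (1−d)·1πᵀ` with persistence d = 0.88 and π equal to
  the benchmark's stage proportions (W 19.6%, N1 6.6%, N2 42.1%, N3 13.5%,
  REM 18.2%), so the stationary law reproduces the class imbalance exactly
  (N1 rarest, N2 dominant) while the diagonal (0.89–0.93) mimics
  minutes-long stage runs. Nights start in W.
* **Signals** are sums of random-phase narrowband oscillations with slow
  amplitude envelopes plus 1/f Gaussian background (β = 1, 6 µV RMS), with
  per-stage recipes at realistic amplitudes: alpha-dominant W (10 Hz,
  30 µV), theta + slow rolling EOG in N1, spindle bursts (12–14 Hz) and
  K-complex-like biphasic pulses in N2, high-amplitude delta in N3 (1.2 Hz,
  110 µV), and low-amplitude mixed EEG with rapid EOG deflections and
  muscle atonia in REM. EMG tone is ordered W > N1 ≥ N2 ≥ N3 > REM
  (30/15/12/10/3 µV RMS), enforced by validation.
* Per-subject child seeds derive from one master seed
  (`numpy.random.SeedSequence.spawn`), so cohorts are bit-reproducible.
* `StageSignalModel.eeg_ambiguous_rem()` gives REM the wake EEG recipe, so
  the REM/W contrast lives only in EOG and EMG — the probe used to show the
  EEG-only ablation scores strictly below the multimodal model.

What the generator does **not** emulate: real inter-subject variability,
artifacts, electrode drift, arousals, stage-transition dynamics beyond
first order, or any waveform morphology beyond band power and simple
transients. Synthetic results therefore demonstrate that the implementation
learns the cues it was built to exploit — they say nothing about accuracy
on clinical recordings, which requires the benchmark download and the full
training schedule.

## Problem sizes in the shipped tests and acceptance script

The default synthetic study conditions are 10 subjects × 200 epochs.
Because these conditions are strongly separable (a logistic regression on
band-power features already exceeds 80% accuracy — asserted in the suite as
the "data bug vs model bug" guard), the cross-validation runs in the test
suite and acceptance script use two passes over the training data per fold;
the memorization check (100 balanced epochs, ≤ 300 Adam steps) and the
ablation-variant checks use one-fold, short-schedule training. The
architecture-sensitivity probe (6 subjects × 80 epochs, 5 passes) enables
class weighting so the rare REM class is not ignored under the short
schedule. All of these are problem-size choices for the synthetic
conditions, not recommended settings for real data, where the full
protocol (max 100 epochs, patience 5) applies.

## Known limitations

* One epoch at a time: no multi-epoch sequence context (the recurrence runs
  over intra-epoch feature steps, not across epochs), and no pretraining.
* The EDF writer covers the subset of EDF+ needed for fixtures
  (16-bit, 1 s records, one annotation run); it is not a general exporter
  (no BDF, no discontinuous EDF-D).
* Metrics follow the macro-averaging convention for the overall
  SEN/SPE/PRE columns; per-class ratios that are undefined on a fold
  (empty class) are reported as 0 with a logged warning.
* The F1 used is the standard harmonic mean 2·PRE·SEN/(PRE+SEN); values are
  therefore guaranteed to lie in [0, 1].
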