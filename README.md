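# sleepstager

Automatic sleep staging from multimodal polysomnography (PSG).

Overnight sleep recordings are scored by experts into 30 s epochs of five
AASM stages — wake (W), light sleep (N1, N2), deep sleep (N3), and REM — a
slow, specialist task that automatic staging aims to replace. `sleepstager`
implements a multi-scale attention network that classifies each epoch from
four raw 100 Hz channels (EEG Fpz–Cz, EEG Pz–Oz, horizontal EOG, chin EMG),
together with everything around it: EDF/EDF+ ingestion for the Sleep-EDF
dialect, epoching with R&K→AASM label mapping and wake trimming,
subject-disjoint cross-validation, the standard metric suite, five ablation
variants, and a synthetic PSG generator so the whole system trains and
tests end to end with no data download.

## Model

For an epoch `x ∈ R^{4×3000}`, grouped into modalities EEG (2 channels),
EOG, EMG:

1. **Multi-scale convolution** per modality: parallel branches with a small
   kernel (50 samples, stride 6, pool 8 → 61 steps) for transients such as
   spindles, and a large kernel (400 samples, stride 50, pool 4 → 13 steps)
   for slow waves; each branch is conv → BN → LeakyReLU → max-pool →
   dropout, and the branch outputs are concatenated along time (74 steps ×
   64 features).
2. **Squeeze-and-excitation gating** per modality:
   `s = σ(W₂ δ(W₁ z))` with `z` the global time-average of each feature
   channel; features are scaled channel-wise by `s` and the three modality
   maps fused to a `(74, 192)` sequence.
3. **BiLSTM (128/direction) + attention pooling**:
   `α_t ∝ exp(vᵀ tanh(W_h h_t + b_h))`, context `c = Σ_t α_t h_t`, then
   dropout (p = 0.5) and a softmax layer give the 5-class posterior;
   training minimizes cross-entropy `L = −Σ_k ŷ_k log y_k` (optional
   inverse-frequency class weights).

Ablation variants built from the same config: `no_msconv`, `eeg_only`,
`no_se`, `no_lstm`, `no_attn` (see `docs/methods.md`).

The network and its training loop run on a self-contained numpy
reverse-mode autodiff engine (`sleepstager.autodiff`); every primitive is
verified against numerical gradients in the test suite.

## Worked example

Generate a synthetic cohort and cross-validate the full model from the
command line:

```sh
sleepstager synth --out cache --subjects 8 --epochs-per-subject 120 --seed 7
# {"W": 339, "N1": 68, "N2": 342, "N3": 96, "REM": 115}
sleepstager train --cache cache --out run --variant full --max-epochs 2 --seed 7
# {"ACC": 96.46, "F1_Macro": 93.87, "Kappa": 95.01, "Sen": 91.44, "Spe": 98.92, "Pre": 97.46}
```

The first line reports the per-stage epoch counts of the generated cohort
(note the realistic imbalance: N1 rarest, N2 dominant). The second reports
the pooled 5-fold subject-disjoint cross-validation metrics in percent:
overall accuracy, macro-F1, Cohen's kappa (chance-corrected agreement), and
macro-averaged sensitivity/specificity/precision. `run/` holds the
confusion matrix (CSV), per-class metrics, training log, predictions, and
the resolved `config.yaml` that makes the run repeatable. `sleepstager
ablate` produces the same table for all six architecture variants under one
shared fold plan, and `sleepstager report` renders hypnogram and
confusion-matrix figures.

The same pipeline ingests real recordings: point `sleepstager prepare
--psg-dir <dir>` at Sleep-EDF style `*-PSG.edf` / `*-Hypnogram.edf` pairs
and the cache it writes drops into the same `train`/`ablate` commands.

Library use mirrors the CLI:

```python
from sleepstager import make_dataset, run_cross_validation, compute_metrics, TrainConfig

dataset = make_dataset(n_subjects=8, epochs_per_subject=120, seed=7)
result = run_cross_validation(dataset, train_config=TrainConfig(max_epochs=2, seed=7))
print(compute_metrics(result.pooled_confusion).to_text())
```

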