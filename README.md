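# gdtil — generative-diffusion task-incremental learning for MI-EEG

Motor neurorehabilitation trains motor-imagery (MI) tasks one at a
time: a patient first practices a single imagined movement pair, and
further movements are added as therapy progresses. A brain–computer
interface decoding those tasks must therefore learn *incrementally* —
absorb each new task without access to the old tasks' raw EEG (privacy,
storage) and without catastrophically forgetting them.

`gdtil` implements a generative-replay solution for this setting:

* **MTSFE** — a multi-scale temporal-spatial feature extractor: parallel
  temporal convolutions with kernels `(1, fs/2^s)`, a depthwise spatial
  convolution `(C, 1)`, dual average/variance pooling, multi-head
  self-attention over pooled time positions, and a convolutional
  encoder producing a flat temporal-spatial feature (TSF) per trial.
* **SSTG** — self-supervised task generalization: per-task projection
  and auxiliary classifier heads trained on segment-recombined
  augmented views against stop-gradient original views,
  `L_SS = L_CE + λ₁(1 − cos(ẑ, stopgrad(z)))`, combined with the
  supervised loss as `L_total = L_CE + λ₂·L_SS` (λ₁ = 0.5, λ₂ = 0.8).
* **PGGR** — prototype-guided generative replay: a class-conditional
  denoising diffusion model over TSF vectors (lightweight 1-D U-Net
  with depthwise-separable convolutions and additive skips,
  conditioned on time-step embedding, label embedding and the class
  prototype μ_c — the per-class mean TSF). At each increment it
  replays features of all old classes.
* **Incremental protocol** — initial phase trains everything; each
  increment freezes all backbone blocks except the convolutional
  encoder, expands the unified classifier, and fine-tunes on replayed
  old features mixed with new-task EEG.
* **Metrics** — accuracy matrix `acc[N, n]`, Cohen's kappa, forward
  transfer rate `FTR = mean_n (acc**_n − acc_{n,n})/acc**_n` and
  backward forgetting rate `BFR = mean_n (acc*_n − acc_{N,n})/acc*_n`
  (percentages; lower is better for both).

Everything runs on synthetic MI-like EEG generated in-package (class-
specific 8–32 Hz oscillations over class-specific channel patterns plus
broadband noise), so no downloads are needed. See `docs/methods.md` for
the full model description and design rationale.

## Worked example

Two-class initial phase plus a one-class increment on synthetic data:

```python
import numpy as np
from gdtil import TaskIncrementalModel, generate_mi_epochs, split_sessions
from gdtil.experiments import synthetic_config, tiny_backbone_config, tiny_train_config

epochs = generate_mi_epochs(synthetic_config(n_classes=3, seed=42))
train, test = split_sessions(epochs, train_fraction=0.75)
model = TaskIncrementalModel.from_epochs(train, test, [(0, 1), (2,)],
                                         tiny_backbone_config(), tiny_train_config())
results = model.fit(seed=2)
print(results.summary())
print(np.round(results.accuracy_matrix.acc, 2))
```

prints

```
Task-incremental learning results
==============================================
phase  classes   Acc. (%)    Kappa
    1        2     100.00   1.0000
    2        3      90.00   0.8333
----------------------------------------------
BFR (backward forgetting rate): 13.33%
[[100.      nan]
 [ 86.67  93.33]]
```

Phase 1 decodes the initial pair perfectly (average accuracy 100 %,
kappa 1). After the increment the model classifies three classes at
90 % average accuracy; the accuracy matrix shows the old pair retained
at 86.67 % while the new class reaches 93.33 %, a backward forgetting
rate of 13.33 %. Running the same fit with `replay=False`
(`tiny_train_config(replay=False)`) collapses old-pair accuracy and
drives the BFR far higher — the diffusion replay is what preserves the
old tasks.

A command-line workflow is available for shell use:

```bash
gdtil simulate --config cfg.yaml --out data.h5
gdtil train    --config cfg.yaml --data data.h5 --state run/
gdtil evaluate --config cfg.yaml --data data.h5 --state run/ --report report.csv
gdtil report   --state run/
```

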