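# Methods

`gdtil` implements task-incremental decoding of motor-imagery (MI) EEG:
a decoder that learns a sequence of class-disjoint MI tasks one chunk at
a time, staying accurate on earlier tasks without storing their raw EEG.
This note documents the model, its assumptions, the tunable parameters,
the synthetic data it is validated on, and the numerical choices made
where the design was open.

## Problem setting

Training arrives as task chunks T_1 … T_N. Each chunk holds epoched EEG
`X_n ∈ R^{T_n × C × V}` (trials × channels × samples, microvolts) with
class labels disjoint from all previous chunks. After learning chunk N
the decoder must classify trials from every seen task among the
cumulative label set. Performance is summarized by an accuracy matrix
`acc[N, n]` (accuracy on task n after learning task N), from which the
average accuracy, the forward transfer rate (FTR, plasticity) and the
backward forgetting rate (BFR, stability) are derived; Cohen's kappa is
reported alongside accuracy.

## Pipeline

**Preprocessing** (`gdtil.epochs`): integer-factor decimation with
anti-alias filtering, zero-phase 8th-order Butterworth band-pass
(default 8–32 Hz, the sensorimotor rhythm range), and global average
re-referencing. Filtering is forward-backward (`sosfiltfilt`), the
standard choice for offline EEG where phase distortion is unacceptable;
the resulting effective attenuation is twice the design order.
Independent-component artifact removal is out of scope: synthetic data
is artifact-free and ingested recordings are assumed pre-cleaned.

**Augmentation** (`gdtil.augmentation`): each training iteration
re-draws augmented trials by splitting same-class trials into
`n_segments` equal time segments (default 8; any remainder samples stay
with the last segment) and recombining segments across trials of the
same class, preserving temporal order. One augmented copy per trial is
the default (`n_copies = 1`); the originals always lead the batch
unchanged. A class represented by a single trial cannot be recombined
and is rejected. A donor may be the trial itself — the recombination is
uniform over the class pool.

**Backbone** (`gdtil.mtsfe`): the multi-scale temporal-spatial feature
extractor maps an epoch to a flat feature vector (TSF) through
- multi-scale temporal convolutions, kernels `(1, fs/2^s)` for
  s = 1 … n_scales (default 4), `temporal_filters_per_scale = 8`;
- a depthwise spatial convolution with kernel `(C, 1)` collapsing the
  electrode axis (depth multiplier 2), batch-normalized, ELU;
- dual pooling along time — average pooling and population-variance
  pooling, kernel `(1, 4)`, stride 20. Average pooling tracks the slow
  envelope; variance pooling measures band power directly, which is the
  physiologically meaningful quantity for event-related
  (de)synchronization. With the default stride the windows sample the
  time axis sparsely; both kernel and stride are configurable.
- D = 4 pre-norm multi-head self-attention blocks per pooled branch
  (8 heads, head width = token width / heads, MLP expansion ×2). Tokens
  are the pooled **time positions**; the channel axis is folded into the
  token width. The alternative reading (tokens = trials) would make
  inference depend on batch composition and was rejected.
- depth-wise concatenation of the two branches and a convolutional
  encoder with kernel `(1, 2)` (`encoder_filters = 16` by default),
  ELU, flatten.

Weight initialization is fan-in uniform under an explicit seed.
Normalization placement (batch norm after temporal and spatial
convolutions) follows the EEGNet convention; the backbone is of that
lineage.

**Self-supervised task generalization** (`gdtil.sstg`): each phase
attaches a fresh projection head (two-layer MLP into a 64-dim semantic
space) and an auxiliary linear classifier head. The augmented view
trains against the original view of the same trial with a
stop-gradient cosine alignment loss
`L_FG = 1 − mean cos(z_aug, stopgrad(z_orig))`, plus the auxiliary
cross-entropy; `L_SS = L_CE^aux + λ1·L_FG` with λ1 = 0.5. The total
phase loss is `L_total = L_CE + λ2·L_SS` with λ2 = 0.8. A
`eq16_literal` switch restricts the self-supervised term to its
cross-entropy component, for comparison with the alternative
formulation in which the alignment term does not enter the total.
Heads are discarded at the end of each phase; only their shaping effect
on the backbone persists.

**Prototype-guided generative replay** (`gdtil.pggr`): old-task features
are replayed by a class-conditional denoising diffusion model over TSF
vectors. The forward chain uses a linear variance ramp; the default is
β from 1e-3 to 0.1 over K = 100 steps, chosen so the terminal marginal
is effectively isotropic (√ᾱ_K ≈ 0.073 < 0.1), the condition ancestral
sampling from N(0, I) relies on. A gentler ramp of the textbook kind
(1e-4 to 0.02) at K = 100 leaves 60 % of the signal at step K and biases
reverse sampling; it is reachable through configuration but not the
default. The denoiser is a lightweight 1-D U-Net: depthwise-separable
convolutions everywhere except the first and last layers, additive skip
connections, feature vectors treated as length-d single-channel
sequences zero-padded to a power-of-two length. Conditioning is
two-fold: (i) a sinusoidal time-step embedding, a learned label
embedding and a linear projection of the class prototype (the per-class
mean TSF) are summed and injected additively at every stage; (ii) the
prototype is also presented as a second input channel next to the noisy
feature vector, giving the denoiser direct access to the conditional
mean. The second pathway proved decisive for conditional fidelity at
realistic feature dimensions; with embedding-only conditioning the
generated class means collapse toward the class mixture. Training
minimizes the standard noise-prediction objective (sample a step k
uniformly, noise the features with the closed-form marginal, regress
the injected noise). Replay draws ancestral reverse samples per class,
one sample set per increment, sized to match the new task's per-class
trial count.

**Incremental protocol** (`gdtil.protocol`): the initial phase trains
backbone, unified linear classifier G_W and heads jointly (Adam,
lr 0.01, batch 64, cap 2000 epochs, early stopping on a 10 %
stratified validation split with patience 50). Each increment then
1. freezes the temporal, spatial and attention blocks (only the
   convolutional encoder stays trainable; frozen batch-norm layers also
   stop updating their statistics),
2. grows G_W by the new classes (old weight columns copied verbatim),
3. samples replay features for *all* old classes,
4. fine-tunes encoder + G_W on new-task EEG (through the frozen
   backbone) mixed with the replayed features, retrains fresh heads,
5. recomputes prototypes for the new classes and fine-tunes the
   replayer on generated-old ∪ real-new features (a `pggr_retrain`
   switch retrains it from scratch instead).

Replayed features enter at the classifier input (encoder output) by
default: the replayer models post-encoder TSFs, and fine-tuning the
encoder on features it did not produce is ill-posed. The alternative
reading — replayed features as encoder inputs — is implemented behind
`replay_injection = "encoder_input"`, in which case the replayer models
the pre-encoder feature map and replayed features pass through the
trainable encoder.

During increments with replay, the early-stopping criterion averages
validation accuracy on the new task with accuracy on the replayed
old-class features. A new-task-only criterion is degenerate when an
increment carries a single class: the trivial always-predict-new state
maximizes it immediately and freezes the run there.

## Numerical choices

* All computation is float64 on a small in-package reverse-mode
  autodiff engine over numpy (`gdtil.nn`); convolutions are lowered to
  BLAS matrix products via im2col. Gradients of every primitive are
  finite-difference tested.
* Batch-norm statistics are re-estimated exactly (one full-batch pass)
  after each initial-phase epoch and after restoring early-stopped
  weights. Running averages lag the moving weights badly on short
  schedules, and restoring best-epoch weights against final-epoch
  statistics is inconsistent; with lagged statistics eval-mode accuracy
  sits tens of points below train-mode accuracy on the same data.
* A master seed fans out to per-module seeds via
  `derive_seed(master, tag)` (CRC32 of the tag, modulo 2^31); identical
  master seeds reproduce the full accuracy matrix bit-for-bit.
* Cohen's kappa returns 1 when the confusion matrix is concentrated in
  one diagonal cell (observed and chance agreement both 1) and rejects
  an all-zero matrix.
* Table aggregation uses the N−1 sample standard deviation, which
  reproduces the published per-subject spreads exactly; the population
  form does not.

## Synthetic data

The generator emulates the signal that motor-imagery decoding rests on:
event-related power modulation of sensorimotor rhythms. Each class is a
band-limited oscillation (a small set of random-phase in-band sinusoids,
default bands tile 8–32 Hz) with a class-specific non-negative spatial
gain pattern over channels, added to unit-variance Gaussian broadband
noise; `snr` is the oscillation-to-noise amplitude ratio. It does *not*
model artifacts (ocular, muscular), 1/f background spectra, inter-trial
nonstationarity, inter-subject variability, or volume-conduction
correlation structure. Passing tests therefore demonstrate the
correctness and the continual-learning mechanics of the pipeline, not
clinical-grade decoding performance on real EEG.

Reference study conditions (`gdtil.experiments`) use 60 trials per
class, 8 channels, 1-second epochs at 128 Hz, snr 2, with a reduced
backbone (2 scales, 4 temporal filters, attention depth 1, pool stride
8, 8 encoder filters) and short schedules (60-epoch cap, patience 20,
600 diffusion steps). These sizes are the package's desk-scale defaults
for synthetic validation; the full-size configuration matches the
reference protocol for 22-channel, 250 Hz recordings.

## Known limitations

* Retention degrades for the most recently added class after a further
  increment (its replay model has seen only one update cycle); the
  first task, whose features the frozen backbone was shaped on, is
  retained best.
* The replayer models features, not raw EEG; nothing can be replayed at
  the signal level, and feature-space drift of the fine-tuned encoder
  is only indirectly constrained in the default injection mode.
* FTR requires a jointly trained reference (`fit_joint`), which doubles
  training cost and is therefore not part of the default fit.
* The GDF ingest path is a thin optional wrapper (via mne) and assumes
  pre-cleaned recordings.
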