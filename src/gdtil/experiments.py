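"""Canonical desk-scale experiments on synthetic motor-imagery data.

These runners define the package's reference study conditions — the tiny
backbone configuration and the synthetic generator settings used for
validation — so that tests, scripts and users all exercise the same
protocol.  Problem sizes are chosen for single-CPU desk runs: 8-channel,
1-second epochs at 128 Hz, a two-scale backbone, and short training
schedules with early stopping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .epochs import SyntheticConfig, generate_mi_epochs, split_sessions
from .mtsfe import MTSFEConfig
from .pggr import (DiffusionSchedule, DiffusionTrainer, LUNet, LUNetConfig,
                   compute_prototypes, forward_diffuse, iterate_forward_chain,
                   sample_replay_features)
from .protocol import TaskIncrementalModel, TrainConfig

__all__ = [
    "tiny_backbone_config", "tiny_train_config", "synthetic_config",
    "run_initial_smoke", "run_generative_recovery", "run_forgetting_study",
    "run_diffusion_marginal_check", "ForgettingOutcome",
]


def synthetic_config(n_classes: int, seed: int, snr: float = 2.0) -> SyntheticConfig:
    return SyntheticConfig(n_classes=n_classes, trials_per_class=60, n_channels=8,
                           duration_s=1.0, fs=128.0, snr=snr, seed=seed)


def tiny_backbone_config() -> MTSFEConfig:
    return MTSFEConfig(fs=128.0, n_channels=8, n_scales=2,
                       temporal_filters_per_scale=4, spatial_depth_multiplier=2,
                       pool_kernel=4, pool_stride=8, mhsa_depth=1, n_heads=2,
                       encoder_filters=8, seed=0)


def tiny_train_config(replay: bool = True) -> TrainConfig:
    return TrainConfig(max_epochs=60, patience=20, replay=replay,
                       diffusion_train_steps=600)


def run_initial_smoke(seed: int) -> float:
    """Initial phase on 2-class synthetic epochs; returns holdout accuracy (%)."""
    ep = generate_mi_epochs(synthetic_config(2, seed=1000 + seed))
    train, test = split_sessions(ep, train_fraction=0.75)
    model = TaskIncrementalModel.from_epochs(train, test, [(0, 1)],
                                             tiny_backbone_config(),
                                             tiny_train_config())
    res = model.fit(seed=seed)
    return res.average_accuracy(0)


def run_generative_recovery(seed: int, d: int = 16, n_per_class: int = 100,
                            sep: float = 3.0) -> dict[str, float]:
    """Train the conditional replayer on two well-separated Gaussian feature
    classes; measure how closely generated class means match the truth and
    how useful generated features are for classification.

    Returns per-dim RMS error of each generated class mean and the accuracy
    of a linear classifier trained only on generated features, scored on
    freshly drawn real features.
    """
    rng = np.random.default_rng(seed)
    means = {0: np.full(d, -sep), 1: np.full(d, sep)}
    f0 = np.vstack([rng.normal(means[c], 1.0, size=(n_per_class, d)) for c in (0, 1)])
    labels = np.repeat([0, 1], n_per_class)
    protos = compute_prototypes(f0, labels)
    sched = DiffusionSchedule.linear(100)
    net = LUNet(d, 2, LUNetConfig(seed=seed))
    trainer = DiffusionTrainer(net, sched, lr=3e-3, seed=seed + 1)
    trainer.fit(f0, labels, protos, n_steps=800, batch_size=64)
    gen, glab = sample_replay_features([0, 1], 200, protos, sched, net, seed=seed + 2)
    rms = {c: float(np.sqrt(np.mean((gen[glab == c].mean(axis=0) - means[c]) ** 2)))
           for c in (0, 1)}
    held = np.vstack([rng.normal(means[c], 1.0, size=(n_per_class, d)) for c in (0, 1)])
    held_labels = np.repeat([0, 1], n_per_class)
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(max_iter=2000).fit(gen, glab)
    acc = float(clf.score(held, held_labels))
    return {"rms_class0": rms[0], "rms_class1": rms[1],
            "classifier_accuracy_pct": 100.0 * acc}


@dataclass
class ForgettingOutcome:
    replay_matrix: np.ndarray
    ablation_matrix: np.ndarray
    old_class_gap: float  # replay minus no-replay, percentage points
    bfr_replay: float
    bfr_ablation: float


def run_forgetting_study(seed: int) -> ForgettingOutcome:
    """4-class sequence (2 initial classes + 2 single-class increments),
    run twice with identical seeds: with diffusion replay and without."""
    results = {}
    for replay in (True, False):
        ep = generate_mi_epochs(synthetic_config(4, seed=100 + seed))
        train, test = split_sessions(ep, train_fraction=0.75)
        model = TaskIncrementalModel.from_epochs(train, test, [(0, 1), (2,), (3,)],
                                                 tiny_backbone_config(),
                                                 tiny_train_config(replay=replay))
        results[replay] = model.fit(seed=seed)
    m_r = results[True].accuracy_matrix.acc
    m_a = results[False].accuracy_matrix.acc
    gap = float(m_r[2, :2].mean() - m_a[2, :2].mean())
    return ForgettingOutcome(m_r, m_a, gap,
                             results[True].bfr(), results[False].bfr())


def run_diffusion_marginal_check(seed: int, n_draws: int = 10_000,
                                 n_steps: int = 10) -> float:
    """Two-sample KS p-value comparing the iterated forward chain against
    the closed-form marginal at step K (scalar features)."""
    sched = DiffusionSchedule.linear(n_steps, 0.01, 0.3)
    f0 = np.ones(n_draws)
    rng1 = np.random.default_rng(seed)
    rng2 = np.random.default_rng(seed + 1)
    chain = iterate_forward_chain(f0, n_steps, sched, rng1)
    closed, _ = forward_diffuse(f0, n_steps, sched, rng2)
    return float(stats.ks_2samp(chain, closed).pvalue)
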