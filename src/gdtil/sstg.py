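"""Self-supervised task generalization (SSTG).

Every task phase attaches a fresh pair of heads to the feature extractor:
a projection head mapping TSFs into a semantic space and an auxiliary
classifier head over that phase's classes.  Two views of each training
trial are pushed through the backbone — the augmented view (trainable
branch) and the original view (stop-gradient branch) — and the loss pulls
the augmented semantic vectors toward their original counterparts by
cosine similarity while the auxiliary cross-entropy keeps them
class-discriminative:

    L_SS = L_CE(aux) + lambda1 * (1 - mean cosine(z_aug, stopgrad(z_orig)))

The total phase loss adds the unified classifier's supervised
cross-entropy: ``L_total = L_CE + lambda2 * L_SS`` (a literal-variant
switch replaces L_SS with its cross-entropy term only).  The heads are
discarded at the end of the phase; only their shaping effect on the
backbone persists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = ["LossConfig", "HeadPair", "ss_ce_loss", "ss_fg_loss", "ss_total",
           "total_training_loss", "cross_entropy_from_logits", "cosine_alignment_loss"]


@dataclass
class LossConfig:
    lambda1: float = 0.5
    lambda2: float = 0.8
    eq16_literal: bool = False

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be non-negative")


class HeadPair(nn.Module):
    """Per-task projection head (2-layer MLP -> semantic space) and
    auxiliary classifier head (linear -> softmax)."""

    def __init__(self, d_in: int, n_classes: int, rng: np.random.Generator,
                 semantic_dim: int = 64, hidden: int = 128, task_id: int = 0):
        super().__init__()
        self.task_id = task_id
        blk = f"head_task{task_id}"
        self.p1 = self.add_module(nn.Linear(d_in, hidden, rng, block=blk, name="proj1"))
        self.p2 = self.add_module(nn.Linear(hidden, semantic_dim, rng, block=blk, name="proj2"))
        self.cls = self.add_module(nn.Linear(d_in, n_classes, rng, block=blk, name="aux_cls"))

    def project(self, f: nn.Tensor) -> nn.Tensor:
        return self.p2(self.p1(f).elu())

    def classify(self, f: nn.Tensor) -> nn.Tensor:
        """Class probabilities (rows on the simplex)."""
        return self.cls(f).softmax(axis=-1)

    def classify_logits(self, f: nn.Tensor) -> nn.Tensor:
        return self.cls(f)


# -- losses -----------------------------------------------------------------

def ss_ce_loss(probs: nn.Tensor | np.ndarray, onehot: np.ndarray) -> nn.Tensor:
    """Mean cross-entropy between predicted probability rows and one-hot targets."""
    p = probs if isinstance(probs, nn.Tensor) else nn.Tensor(probs)
    y = np.asarray(onehot, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError("probability and target shapes differ")
    rowsum = p.data.sum(axis=-1)
    if np.any(np.abs(rowsum - 1.0) > 1e-6) or np.any(p.data < -1e-12):
        raise ValueError("prediction rows must lie on the probability simplex")
    eps = 1e-12
    return -((p + eps).log() * y).sum(axis=-1).mean()


def cross_entropy_from_logits(logits: nn.Tensor, labels: np.ndarray) -> nn.Tensor:
    """Numerically stable mean CE from raw logits and integer labels."""
    logp = logits.log_softmax(axis=-1)
    n = logits.shape[0]
    picked = logp[np.arange(n), np.asarray(labels, dtype=int)]
    return -picked.mean()


def _row_normalize(z: nn.Tensor) -> nn.Tensor:
    norms = (z * z).sum(axis=-1, keepdims=True)
    if np.any(norms.data <= 0):
        raise ValueError("zero-norm semantic row; cosine similarity undefined")
    return z * norms ** -0.5


def ss_fg_loss(z_aug: nn.Tensor, z_orig: nn.Tensor | np.ndarray) -> nn.Tensor:
    """``1 - mean cosine(z_aug, stopgrad(z_orig))`` over paired rows, in [0, 2].

    The original-view branch carries no gradient: it is detached here even
    if a graph-connected tensor is passed.
    """
    zo = z_orig.detach() if isinstance(z_orig, nn.Tensor) else nn.Tensor(z_orig)
    if z_aug.shape != zo.shape:
        raise ValueError("paired semantic batches must share a shape")
    cos = (_row_normalize(z_aug) * _row_normalize(zo)).sum(axis=-1)
    return 1.0 - cos.mean()


def ss_total(ce: nn.Tensor | float, fg: nn.Tensor | float, cfg: LossConfig) -> nn.Tensor:
    """Self-supervised loss: ``ce + lambda1 * fg``."""
    ce = ce if isinstance(ce, nn.Tensor) else nn.Tensor(ce)
    return ce + cfg.lambda1 * (fg if isinstance(fg, nn.Tensor) else nn.Tensor(fg))


def total_training_loss(ce_main, ss, cfg: LossConfig, ss_ce=None):
    """Phase loss ``L_CE + lambda2 * L_SS``; with ``eq16_literal`` the
    self-supervised term is its cross-entropy component alone."""
    ce_main = ce_main if isinstance(ce_main, nn.Tensor) else nn.Tensor(ce_main)
    if cfg.eq16_literal:
        if ss_ce is None:
            raise ValueError("eq16_literal needs the self-supervised CE term")
        term = ss_ce if isinstance(ss_ce, nn.Tensor) else nn.Tensor(ss_ce)
    else:
        term = ss if isinstance(ss, nn.Tensor) else nn.Tensor(ss)
    return ce_main + cfg.lambda2 * term


# convenience alias used by the trainer
cosine_alignment_loss = ss_fg_loss
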