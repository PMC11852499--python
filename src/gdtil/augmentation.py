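"""Segment-and-recombine augmentation for epoched EEG.

Each augmented trial of class ``c`` is assembled segment by segment, in
the original temporal order: segment k is copied verbatim from a uniformly
chosen training trial of the same class (the source trial itself is an
admissible donor).  Recombination therefore never crosses class
boundaries and never re-orders time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epochs import EEGEpochs

__all__ = ["AugmentConfig", "segment_bounds", "augment_epochs"]


@dataclass
class AugmentConfig:
    n_segments: int = 8
    n_copies: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.n_copies < 0:
            raise ValueError("n_copies must be >= 0")


def segment_bounds(n_samples: int, n_segments: int) -> np.ndarray:
    """Segment boundaries along time: equal segments, with any remainder
    samples staying with the last segment."""
    if n_segments > n_samples:
        raise ValueError(f"{n_segments} segments exceed {n_samples} samples")
    seg = n_samples // n_segments
    bounds = np.arange(0, n_segments + 1) * seg
    bounds[-1] = n_samples
    return bounds


def augment_epochs(x: EEGEpochs, cfg: AugmentConfig) -> EEGEpochs:
    """Return ``(n_copies + 1) * n_trials`` trials; the originals lead unchanged."""
    if cfg.n_copies == 0:
        return EEGEpochs(x.data.copy(), x.labels.copy(), x.fs,
                         None if x.session_id is None else x.session_id.copy())
    bounds = segment_bounds(x.n_samples, cfg.n_segments)
    rng = np.random.default_rng(cfg.seed)
    class_pool = {c: np.flatnonzero(x.labels == c) for c in np.unique(x.labels)}
    for c, pool in class_pool.items():
        if len(pool) < 2:
            raise ValueError(f"class {c} has {len(pool)} trial(s); recombination needs >= 2")
    chunks = [x.data]
    for _ in range(cfg.n_copies):
        copy = np.empty_like(x.data)
        for i, c in enumerate(x.labels):
            pool = class_pool[c]
            donors = rng.integers(0, len(pool), size=cfg.n_segments)
            for k in range(cfg.n_segments):
                lo, hi = bounds[k], bounds[k + 1]
                copy[i, :, lo:hi] = x.data[pool[donors[k]], :, lo:hi]
        chunks.append(copy)
    data = np.concatenate(chunks, axis=0)
    labels = np.tile(x.labels, cfg.n_copies + 1)
    return EEGEpochs(data, labels, x.fs)
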