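"""EEG epoch container, synthetic motor-imagery generator, and preprocessing.

The container holds a ``trials x channels x samples`` array in microvolts
with per-trial integer class labels (0-based) and the sampling rate.  The
synthetic generator emulates the sensorimotor-rhythm phenomenology that
motor-imagery decoding relies on: each class modulates band-limited
(8-32 Hz) oscillatory power over a class-specific spatial pattern of
channels, superimposed on broadband Gaussian noise.  Event-related
(de)synchronization in real recordings is a *power* change in those bands
over sensorimotor sites; a class-dependent band/pattern combination is the
minimal signal that gives a decoder the same kind of evidence.

Preprocessing follows the standard offline motor-imagery chain: integer
decimation with anti-alias filtering, zero-phase Butterworth band-pass,
and global average re-referencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "EEGEpochs",
    "SyntheticConfig",
    "generate_mi_epochs",
    "butterworth_bandpass",
    "downsample",
    "average_reference",
    "split_sessions",
    "save_epochs",
    "load_epochs",
    "read_gdf",
]


@dataclass
class EEGEpochs:
    """Epoched multichannel EEG: ``data[trial, channel, sample]`` (µV)."""

    data: np.ndarray
    labels: np.ndarray
    fs: float
    session_id: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal the number of trials")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains NaN or Inf")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative (0-based)")
        if self.session_id is not None:
            self.session_id = np.asarray(self.session_id, dtype=np.int64)
            if len(self.session_id) != self.data.shape[0]:
                raise ValueError("session_id length must equal the number of trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def select(self, idx) -> "EEGEpochs":
        sid = None if self.session_id is None else self.session_id[idx]
        return EEGEpochs(self.data[idx], self.labels[idx], self.fs, sid)


@dataclass
class SyntheticConfig:
    """Conditions for the synthetic motor-imagery generator.

    ``class_band_hz`` gives each class an oscillation band inside the
    8-32 Hz sensorimotor range; ``class_channel_pattern`` gives each class
    a non-negative spatial gain over channels. ``snr`` is the amplitude
    ratio of the class oscillation to the unit-variance broadband noise
    (``np.inf`` disables the noise).
    """

    n_classes: int = 2
    trials_per_class: int = 60
    n_channels: int = 8
    duration_s: float = 1.0
    fs: float = 128.0
    class_band_hz: list[tuple[float, float]] | None = None
    class_channel_pattern: np.ndarray | None = None
    snr: float = 1.0
    n_sessions: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")
        if self.class_band_hz is None:
            # evenly spaced sub-bands of the 8-32 Hz sensorimotor range
            edges = np.linspace(8.0, 32.0, self.n_classes + 1)
            self.class_band_hz = [(edges[i], edges[i + 1]) for i in range(self.n_classes)]
        if len(self.class_band_hz) != self.n_classes:
            raise ValueError("one band per class required")
        for lo, hi in self.class_band_hz:
            if not (8.0 <= lo < hi <= 32.0):
                raise ValueError(f"band ({lo}, {hi}) outside [8, 32] Hz")
        if self.class_channel_pattern is None:
            # each class concentrates on a distinct contiguous channel group
            pat = np.zeros((self.n_classes, self.n_channels))
            for c in range(self.n_classes):
                lo = (c * self.n_channels) // self.n_classes
                hi = ((c + 1) * self.n_channels) // self.n_classes
                pat[c, lo:max(hi, lo + 1)] = 1.0
            self.class_channel_pattern = pat
        self.class_channel_pattern = np.asarray(self.class_channel_pattern, dtype=np.float64)
        if self.class_channel_pattern.shape != (self.n_classes, self.n_channels):
            raise ValueError("class_channel_pattern must be n_classes x n_channels")
        if (self.class_channel_pattern < 0).any():
            raise ValueError("channel patterns must be non-negative")


def generate_mi_epochs(cfg: SyntheticConfig) -> EEGEpochs:
    """Draw synthetic motor-imagery epochs under `cfg`; deterministic per seed.

    Each trial of class ``c`` is a random-phase oscillation with power
    spread uniformly over the class band, scaled per channel by the class
    spatial pattern and ``snr``, plus independent unit-variance Gaussian
    noise on every channel (omitted when ``snr`` is infinite).
    """
    rng = np.random.default_rng(cfg.seed)
    v = int(round(cfg.duration_s * cfg.fs))
    n_total = cfg.n_classes * cfg.trials_per_class
    data = np.zeros((n_total, cfg.n_channels, v))
    labels = np.repeat(np.arange(cfg.n_classes), cfg.trials_per_class)
    t = np.arange(v) / cfg.fs
    noisy = np.isfinite(cfg.snr)
    for i, c in enumerate(labels):
        lo, hi = cfg.class_band_hz[c]
        # a few random in-band sinusoids approximate band-limited power
        freqs = rng.uniform(lo, hi, size=4)
        phases = rng.uniform(0, 2 * np.pi, size=4)
        osc = np.cos(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]).sum(axis=0)
        osc *= np.sqrt(2.0 / len(freqs))  # unit RMS
        amp = cfg.snr if noisy else 1.0
        data[i] = amp * cfg.class_channel_pattern[c][:, None] * osc[None, :]
        if noisy:
            data[i] += rng.standard_normal((cfg.n_channels, v))
    if cfg.n_sessions > 1:
        per = int(np.ceil(n_total / cfg.n_sessions))
        session = np.repeat(np.arange(cfg.n_sessions), per)[:n_total]
        # interleave classes across sessions so each session sees all classes
        order = np.argsort(np.tile(np.arange(cfg.trials_per_class), cfg.n_classes), kind="stable")
        data, labels = data[order], labels[order]
    else:
        session = np.zeros(n_total, dtype=int)
    return EEGEpochs(data, labels, cfg.fs, session_id=session)


def butterworth_bandpass(x: EEGEpochs, low_hz: float, high_hz: float, order: int = 8) -> EEGEpochs:
    """Zero-phase Butterworth band-pass per channel per trial."""
    nyq = x.fs / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(f"band ({low_hz}, {high_hz}) must lie inside (0, {nyq}) Hz")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=x.fs, output="sos")
    out = signal.sosfiltfilt(sos, x.data, axis=-1)
    return replace(x, data=np.ascontiguousarray(out))


def downsample(x: EEGEpochs, target_fs: float) -> EEGEpochs:
    """Integer-factor decimation with anti-alias filtering."""
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    factor = x.fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"fs {x.fs} not an integer multiple of {target_fs}")
    factor = int(round(factor))
    if factor == 1:
        return replace(x)
    out = signal.decimate(x.data, factor, axis=-1, ftype="iir", zero_phase=True)
    return replace(x, data=np.ascontiguousarray(out), fs=target_fs)


def average_reference(x: EEGEpochs) -> EEGEpochs:
    """Subtract the instantaneous cross-channel mean (global average reference)."""
    if x.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    out = x.data - x.data.mean(axis=1, keepdims=True)
    return replace(x, data=out)


def split_sessions(x: EEGEpochs, train_sessions: int | None = None,
                   train_fraction: float | None = None) -> tuple[EEGEpochs, EEGEpochs]:
    """Disjoint train/test partition by recording session.

    ``train_sessions`` keeps the first k sessions for training (session
    labels required); ``train_fraction`` splits the ordered trial list at
    the given fraction when session ids are absent.
    """
    if train_sessions is not None:
        if x.session_id is None:
            raise ValueError("session_id required for a session-count split")
        sessions = np.unique(x.session_id)
        if not (0 < train_sessions < len(sessions)):
            raise ValueError(f"train_sessions must be in (0, {len(sessions)})")
        keep = np.isin(x.session_id, sessions[:train_sessions])
    elif train_fraction is not None:
        if not (0 < train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        keep = np.zeros(x.n_trials, dtype=bool)
        # stratified by class so both halves see every class
        for c in np.unique(x.labels):
            idx = np.flatnonzero(x.labels == c)
            keep[idx[: int(round(train_fraction * len(idx)))]] = True
    else:
        raise ValueError("provide train_sessions or train_fraction")
    if keep.all() or not keep.any():
        raise ValueError("split leaves an empty partition")
    return x.select(keep), x.select(~keep)


# -- container I/O ---------------------------------------------------------

_KEYS = ("data", "labels", "fs", "session_id")


def save_epochs(x: EEGEpochs, path: str) -> None:
    """Write epochs to HDF5 (``.h5``/``.hdf5``) or NPZ (``.npz``)."""
    sid = x.session_id if x.session_id is not None else np.full(x.n_trials, -1)
    if str(path).endswith(".npz"):
        np.savez(path, data=x.data, labels=x.labels, fs=np.float64(x.fs), session_id=sid)
        return
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=x.data)
        f.create_dataset("labels", data=x.labels)
        f.create_dataset("fs", data=np.float64(x.fs))
        f.create_dataset("session_id", data=sid)


def load_epochs(path: str) -> EEGEpochs:
    if str(path).endswith(".npz"):
        with np.load(path) as f:
            vals = {k: f[k] for k in _KEYS}
    else:
        import h5py

        with h5py.File(path, "r") as f:
            vals = {k: f[k][()] for k in _KEYS}
    sid = vals["session_id"]
    if np.all(sid < 0):
        sid = None
    return EEGEpochs(vals["data"], vals["labels"], float(vals["fs"]), sid)


def read_gdf(path: str, tmin: float, tmax: float, event_id: dict[str, int] | None = None) -> EEGEpochs:
    """Optional ingest of a GDF recording (e.g. the public four-class
    motor-imagery benchmark) via mne; labels are re-coded to 0-based."""
    import mne  # optional dependency

    raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    events, mapping = mne.events_from_annotations(raw, event_id=event_id, verbose="error")
    ep = mne.Epochs(raw, events, tmin=tmin, tmax=tmax, baseline=None,
                    preload=True, verbose="error")
    codes = ep.events[:, 2]
    uniq = {c: i for i, c in enumerate(sorted(set(codes)))}
    labels = np.array([uniq[c] for c in codes])
    return EEGEpochs(ep.get_data() * 1e6, labels, float(raw.info["sfreq"]))
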