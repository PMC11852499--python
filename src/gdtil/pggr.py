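"""Prototype-guided generative replay (PGGR).

Old-task features are replayed by a class-conditional denoising diffusion
model over TSF vectors.  The forward chain adds Gaussian noise over K
discrete steps with variances ``beta_k``; its closed-form marginal at
step k is

    f_k = sqrt(abar_k) * f_0 + sqrt(1 - abar_k) * eta,   eta ~ N(0, I),

with ``abar_k = prod_{i<=k} (1 - beta_i)``.  A lightweight 1-D U-Net
(depthwise-separable convolutions, additive skip connections) is trained
to predict the injected noise, conditioned on a sinusoidal time-step
embedding fused (by summation) with a learned label embedding and a
linear projection of the class prototype — the per-class mean TSF.
Replay draws ancestral reverse samples from an isotropic Gaussian,
conditioned per class on (prototype, label).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import functional as F

__all__ = ["PrototypeSet", "compute_prototypes", "DiffusionSchedule",
           "forward_diffuse", "LUNetConfig", "LUNet", "DiffusionTrainer",
           "sample_replay_features"]


# -- prototypes --------------------------------------------------------------

@dataclass
class PrototypeSet:
    """Per-class mean feature vectors used as diffusion conditioning."""

    prototypes: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def dim(self) -> int | None:
        for v in self.prototypes.values():
            return len(v)
        return None

    def merge(self, other: "PrototypeSet") -> "PrototypeSet":
        out = dict(self.prototypes)
        out.update({c: v.copy() for c, v in other.prototypes.items()})
        return PrototypeSet(out)

    def get(self, class_id: int) -> np.ndarray:
        if class_id not in self.prototypes:
            raise KeyError(f"no prototype for class {class_id}")
        return self.prototypes[class_id]

    def as_matrix(self, classes) -> np.ndarray:
        return np.stack([self.get(c) for c in classes])


def compute_prototypes(features: np.ndarray, labels: np.ndarray,
                       base: PrototypeSet | None = None) -> PrototypeSet:
    """Arithmetic per-class mean of feature rows, merged into `base`."""
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if features.shape[0] != len(labels):
        raise ValueError("features and labels disagree in length")
    protos = {}
    for c in np.unique(labels):
        rows = features[labels == c]
        if rows.shape[0] == 0:
            raise ValueError(f"class {c} has no samples")
        protos[int(c)] = rows.mean(axis=0)
    new = PrototypeSet(protos)
    return base.merge(new) if base is not None else new


# -- schedule ----------------------------------------------------------------

@dataclass
class DiffusionSchedule:
    """Per-step noise variances and their cumulative products."""

    betas: np.ndarray

    def __post_init__(self):
        self.betas = np.asarray(self.betas, dtype=np.float64)
        if self.betas.ndim != 1 or len(self.betas) == 0:
            raise ValueError("betas must be a non-empty vector")
        if np.any(self.betas < 0) or np.any(self.betas >= 1):
            raise ValueError("betas must lie in [0, 1)")
        self.alphas = 1.0 - self.betas
        self.alphas_bar = np.cumprod(self.alphas)

    @classmethod
    def linear(cls, n_steps: int = 100, beta_start: float = 1e-3,
               beta_end: float = 0.1) -> "DiffusionSchedule":
        """Linear variance ramp. The default endpoints are chosen so that
        at K=100 the terminal marginal is effectively isotropic
        (sqrt(abar_K) < 0.1), the condition ancestral sampling relies on."""
        return cls(np.linspace(beta_start, beta_end, n_steps))

    @property
    def n_steps(self) -> int:
        return len(self.betas)


def forward_diffuse(f0: np.ndarray, k: int, sched: DiffusionSchedule,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form forward marginal at step k (1-based); returns (f_k, eta)."""
    if not (1 <= k <= sched.n_steps):
        raise ValueError(f"step {k} outside [1, {sched.n_steps}]")
    f0 = np.asarray(f0, dtype=np.float64)
    ab = sched.alphas_bar[k - 1]
    eta = rng.standard_normal(f0.shape)
    return np.sqrt(ab) * f0 + np.sqrt(1.0 - ab) * eta, eta


def iterate_forward_chain(f0: np.ndarray, k: int, sched: DiffusionSchedule,
                          rng: np.random.Generator) -> np.ndarray:
    """Step-by-step forward chain (for validating the closed-form marginal)."""
    x = np.asarray(f0, dtype=np.float64).copy()
    for i in range(k):
        b = sched.betas[i]
        x = np.sqrt(1.0 - b) * x + np.sqrt(b) * rng.standard_normal(x.shape)
    return x


# -- LU-Net denoiser ----------------------------------------------------------

@dataclass
class LUNetConfig:
    widths: tuple[int, ...] = (16, 32)
    cond_dim: int = 32
    kernel: int = 3
    seed: int = 0

    def __post_init__(self):
        if len(self.widths) < 1:
            raise ValueError("need at least one stage width")
        if self.cond_dim < 2 or self.cond_dim % 2:
            raise ValueError("cond_dim must be an even integer >= 2")


def _sinusoidal_embedding(k: np.ndarray, dim: int, max_steps: float = 10000.0) -> np.ndarray:
    k = np.asarray(k, dtype=np.float64).reshape(-1, 1)
    half = dim // 2
    freqs = np.exp(-np.log(max_steps) * np.arange(half) / max(half - 1, 1))
    ang = k * freqs[None, :]
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1)


class _DSConv(nn.Module):
    """Depthwise-separable 1-D convolution (depthwise k-tap + pointwise)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng, name: str):
        super().__init__()
        self.dw = self.register(nn.Parameter(
            rng.uniform(-1, 1, size=(c_in, kernel)) / np.sqrt(kernel),
            name=f"{name}.dw", block="denoiser"))
        self.pw = self.register(nn.Parameter(
            rng.uniform(-1, 1, size=(c_in, c_out)) / np.sqrt(c_in),
            name=f"{name}.pw", block="denoiser"))
        self.b = self.register(nn.Parameter(np.zeros(c_out), name=f"{name}.b",
                                            block="denoiser"))

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        dwout = F.depthwise_conv_time(x, self.dw, same=True)  # (n, c_in, L)
        mixed = (dwout.transpose(0, 2, 1) @ self.pw).transpose(0, 2, 1)
        return mixed + self.b.reshape(1, -1, 1)


class _CondProj(nn.Module):
    def __init__(self, cond_dim: int, channels: int, rng, name: str):
        super().__init__()
        self.lin = self.add_module(nn.Linear(cond_dim, channels, rng,
                                             block="denoiser", name=name))

    def __call__(self, x: nn.Tensor, cond: nn.Tensor) -> nn.Tensor:
        return x + self.lin(cond).reshape(cond.shape[0], -1, 1)


class LUNet(nn.Module):
    """Conditional 1-D denoiser over feature vectors.

    Symmetric encoder/decoder; every convolution except the first and the
    last is depthwise-separable; skip connections are additive.  The
    conditioning vector (time step + label + prototype, summed in a shared
    embedding space) is injected additively at every stage.
    """

    def __init__(self, feature_dim: int, n_classes: int, cfg: LUNetConfig):
        super().__init__()
        self.cfg = cfg
        self.feature_dim = feature_dim
        depth = len(cfg.widths)
        mult = 2 ** depth
        self.padded = int(np.ceil(feature_dim / mult) * mult)
        rng = np.random.default_rng(cfg.seed)
        cd = cfg.cond_dim
        self.t_proj = self.add_module(nn.Linear(cd, cd, rng, block="denoiser", name="t_proj"))
        self.label_emb = self.add_module(nn.Embedding(n_classes, cd, rng, block="denoiser", name="label_emb"))
        self.proto_proj = self.add_module(nn.Linear(feature_dim, cd, rng, block="denoiser", name="proto_proj"))
        k = cfg.kernel
        w0 = cfg.widths[0]
        # two input channels: the noisy feature vector and the class
        # prototype, giving the denoiser direct access to the conditional mean
        self.in_w = self.register(nn.Parameter(
            rng.uniform(-1, 1, size=(w0, 2, k)) / np.sqrt(2 * k), name="in.w", block="denoiser"))
        self.in_b = self.register(nn.Parameter(np.zeros(w0), name="in.b", block="denoiser"))
        self.down = []
        self.down_cond = []
        widths = list(cfg.widths)
        for i in range(depth - 1):
            self.down.append(self.add_module(_DSConv(widths[i], widths[i + 1], k, rng, f"down{i}")))
            self.down_cond.append(self.add_module(_CondProj(cd, widths[i + 1], rng, f"down{i}.cond")))
        self.mid = self.add_module(_DSConv(widths[-1], widths[-1], k, rng, "mid"))
        self.mid_cond = self.add_module(_CondProj(cd, widths[-1], rng, "mid.cond"))
        self.up = []
        self.up_cond = []
        for i in reversed(range(depth - 1)):
            self.up.append(self.add_module(_DSConv(widths[i + 1], widths[i], k, rng, f"up{i}")))
            self.up_cond.append(self.add_module(_CondProj(cd, widths[i], rng, f"up{i}.cond")))
        self.out_w = self.register(nn.Parameter(
            rng.uniform(-1, 1, size=(1, w0, k)) / np.sqrt(w0 * k), name="out.w", block="denoiser"))
        self.out_b = self.register(nn.Parameter(np.zeros(1), name="out.b", block="denoiser"))

    def condition(self, k: np.ndarray, labels: np.ndarray, protos: np.ndarray) -> nn.Tensor:
        emb = nn.Tensor(_sinusoidal_embedding(k, self.cfg.cond_dim))
        t = self.t_proj(emb)
        lab = self.label_emb(np.asarray(labels, dtype=int))
        pr = self.proto_proj(nn.Tensor(protos))
        return t + lab + pr

    def __call__(self, f_k: nn.Tensor | np.ndarray, k: np.ndarray,
                 labels: np.ndarray, protos: np.ndarray) -> nn.Tensor:
        x = f_k if isinstance(f_k, nn.Tensor) else nn.Tensor(f_k)
        n, d = x.shape
        if d != self.feature_dim:
            raise ValueError(f"expected feature dim {self.feature_dim}, got {d}")
        cond = self.condition(np.broadcast_to(np.asarray(k, dtype=float), (n,)), labels, protos)
        x = x.pad_last(0, self.padded - d).reshape(n, 1, 1, self.padded)
        pr = nn.Tensor(np.asarray(protos, dtype=np.float64)).pad_last(
            0, self.padded - d).reshape(n, 1, 1, self.padded)
        xc = nn.concatenate([x, pr], axis=1)
        h = F.conv_time(xc, self.in_w, self.in_b, same=True).reshape(n, -1, self.padded).elu()
        skips = []
        for conv, cp in zip(self.down, self.down_cond):
            skips.append(h)
            h = F.avg_pool_time(h, 2, 2)
            h = cp(conv(h), cond).elu()
        h = self.mid_cond(self.mid(h), cond).elu()
        for conv, cp, skip in zip(self.up, self.up_cond, reversed(skips)):
            h = F.upsample_time(h, 2)
            h = cp(conv(h), cond).elu() + skip
        out = F.conv_time(h.reshape(n, h.shape[1], 1, h.shape[2]),
                          self.out_w, self.out_b, same=True)
        return out.reshape(n, self.padded)[:, :d]


# -- training & sampling -------------------------------------------------------

class DiffusionTrainer:
    """Noise-prediction training of the conditional denoiser."""

    def __init__(self, denoiser: LUNet, sched: DiffusionSchedule,
                 lr: float = 1e-3, seed: int = 0):
        self.denoiser = denoiser
        self.sched = sched
        self.opt = nn.Adam(denoiser.parameters(), lr=lr)
        self.rng = np.random.default_rng(seed)

    def step(self, f0: np.ndarray, labels: np.ndarray, protos: PrototypeSet) -> float:
        """One optimization step; returns the mean squared noise-prediction error."""
        f0 = np.asarray(f0, dtype=np.float64)
        labels = np.asarray(labels, dtype=int)
        for c in np.unique(labels):
            protos.get(int(c))  # raises if a prototype is missing
        n = f0.shape[0]
        k = self.rng.integers(1, self.sched.n_steps + 1, size=n)
        ab = self.sched.alphas_bar[k - 1][:, None]
        eta = self.rng.standard_normal(f0.shape)
        f_k = np.sqrt(ab) * f0 + np.sqrt(1.0 - ab) * eta
        pr = np.stack([protos.get(int(c)) for c in labels])
        pred = self.denoiser(f_k, k, labels, pr)
        diff = pred - nn.Tensor(eta)
        loss = (diff * diff).mean()
        self.opt.zero_grad()
        loss.backward()
        self.opt.step()
        return float(loss.data)

    def fit(self, f0: np.ndarray, labels: np.ndarray, protos: PrototypeSet,
            n_steps: int = 500, batch_size: int = 64) -> list[float]:
        f0 = np.asarray(f0, dtype=np.float64)
        labels = np.asarray(labels, dtype=int)
        losses = []
        for _ in range(n_steps):
            idx = self.rng.integers(0, f0.shape[0], size=min(batch_size, f0.shape[0]))
            losses.append(self.step(f0[idx], labels[idx], protos))
        return losses


def sample_replay_features(classes, n_per_class: int, protos: PrototypeSet,
                           sched: DiffusionSchedule, denoiser: LUNet,
                           seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral reverse sampling conditioned per class on (prototype, label).

    Returns ``(features, labels)`` with ``len(classes) * n_per_class`` rows
    of width equal to the denoiser's feature dimension.
    """
    rng = np.random.default_rng(seed)
    d = denoiser.feature_dim
    labels = np.repeat(np.asarray(list(classes), dtype=int), n_per_class)
    n = len(labels)
    pr = np.stack([protos.get(int(c)) for c in labels]) if n else np.zeros((0, d))
    x = rng.standard_normal((n, d))
    was = denoiser.training
    denoiser.eval()
    for k in range(sched.n_steps, 0, -1):
        beta = sched.betas[k - 1]
        alpha = sched.alphas[k - 1]
        ab = sched.alphas_bar[k - 1]
        eps = denoiser(x, np.full(n, k), labels, pr).data
        mean = (x - beta / np.sqrt(1.0 - ab) * eps) / np.sqrt(alpha)
        if k > 1:
            x = mean + np.sqrt(beta) * rng.standard_normal(x.shape)
        else:
            x = mean
    denoiser.train(was)
    return x, labels
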