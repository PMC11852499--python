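"""Multi-scale temporal-spatial feature extractor (MTSFE).

The backbone maps an epoch ``(channels x samples)`` to a flat
temporal-spatial feature (TSF) vector through five named parameter
blocks, which the incremental-learning freezing policy addresses by name:

``temporal_convs``
    One 2-D convolution per temporal scale with kernel ``(1, fs/2^s)``,
    s = 1..n_scales, capturing oscillatory structure at several temporal
    resolutions; batch-normalized per scale.
``spatial_convs``
    A depthwise convolution with kernel ``(C, 1)`` collapsing the
    electrode axis into learned spatial projections (depth multiplier
    configurable), batch-normalized, ELU.
``mhsa_avg`` / ``mhsa_var``
    The feature map is pooled twice along time — average pooling and
    population-variance pooling, same kernel/stride — and each branch
    runs through D multi-head self-attention blocks whose tokens are the
    pooled time positions (channel axis folded into the token width).
``encoder``
    The two branches are concatenated depth-wise and fused by a
    convolutional encoder with kernel ``(1, 2)``; flattening its output
    yields the TSF.

During incremental phases only ``encoder`` stays trainable; the other
four blocks are frozen, including their batch-norm statistics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .epochs import EEGEpochs
from .nn import functional as F

__all__ = ["MTSFEConfig", "MTSFE", "var_pool", "block_digest",
           "BACKBONE_BLOCKS", "save_checkpoint", "load_checkpoint"]

BACKBONE_BLOCKS = ("temporal_convs", "spatial_convs", "mhsa_avg", "mhsa_var")


@dataclass
class MTSFEConfig:
    fs: float = 250.0
    n_channels: int = 22
    n_scales: int = 4
    temporal_filters_per_scale: int = 8
    spatial_depth_multiplier: int = 2
    pool_kernel: int = 4
    pool_stride: int = 20
    mhsa_depth: int = 4
    n_heads: int = 8
    mlp_expansion: int = 2
    encoder_filters: int = 16
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.n_scales <= 4):
            raise ValueError("n_scales must be in [1, 4]")
        for f_ in ("temporal_filters_per_scale", "spatial_depth_multiplier",
                   "pool_kernel", "pool_stride", "mhsa_depth", "n_heads",
                   "encoder_filters"):
            if getattr(self, f_) < 1:
                raise ValueError(f"{f_} must be positive")
        if self.d_model % self.n_heads:
            raise ValueError(
                f"token width {self.d_model} not divisible by {self.n_heads} heads")

    @property
    def temporal_kernels(self) -> list[int]:
        return [max(2, int(round(self.fs / 2 ** s))) for s in range(1, self.n_scales + 1)]

    @property
    def d_model(self) -> int:
        """Token width after spatial projection (maps per branch)."""
        return self.n_scales * self.temporal_filters_per_scale * self.spatial_depth_multiplier

    def n_tokens(self, n_samples: int) -> int:
        if n_samples < self.pool_kernel:
            raise ValueError("epoch shorter than the pooling kernel")
        return (n_samples - self.pool_kernel) // self.pool_stride + 1

    def feature_dim(self, n_samples: int) -> int:
        """TSF width for epochs of the given length."""
        return self.encoder_filters * (self.n_tokens(n_samples) - 1)


def var_pool(window) -> float:
    """Population variance of one pooling window (the VarPool kernel)."""
    w = np.asarray(window, dtype=np.float64)
    if w.size == 0:
        raise ValueError("empty pooling window")
    return float(w.var())


class MTSFE(nn.Module):
    def __init__(self, cfg: MTSFEConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        f = cfg.temporal_filters_per_scale
        self.t_convs = []
        self.t_bns = []
        for s, k in enumerate(cfg.temporal_kernels):
            w = self.register(nn.Parameter(
                np.random.default_rng(rng.integers(2 ** 31)).uniform(
                    -1, 1, size=(f, 1, k)) / np.sqrt(k),
                name=f"temporal{s}.w", block="temporal_convs"))
            b = self.register(nn.Parameter(np.zeros(f), name=f"temporal{s}.b",
                                           block="temporal_convs"))
            bn = self.add_module(nn.BatchNorm2d(f, block="temporal_convs", name=f"temporal{s}.bn"))
            self.t_convs.append((w, b))
            self.t_bns.append(bn)
        g = cfg.n_scales * f
        m = cfg.spatial_depth_multiplier
        c = cfg.n_channels
        self.s_w = self.register(nn.Parameter(
            rng.uniform(-1, 1, size=(g, m, c)) / np.sqrt(c),
            name="spatial.w", block="spatial_convs"))
        self.s_b = self.register(nn.Parameter(np.zeros(g * m), name="spatial.b",
                                              block="spatial_convs"))
        self.s_bn = self.add_module(nn.BatchNorm2d(g * m, block="spatial_convs", name="spatial.bn"))
        d = cfg.d_model
        self.mhsa_avg = [self.add_module(nn.MHSABlock(
            d, cfg.n_heads, rng, block="mhsa_avg", name=f"mhsa_avg{i}",
            mlp_expansion=cfg.mlp_expansion)) for i in range(cfg.mhsa_depth)]
        self.mhsa_var = [self.add_module(nn.MHSABlock(
            d, cfg.n_heads, rng, block="mhsa_var", name=f"mhsa_var{i}",
            mlp_expansion=cfg.mlp_expansion)) for i in range(cfg.mhsa_depth)]
        self.e_w = self.register(nn.Parameter(
            rng.uniform(-1, 1, size=(cfg.encoder_filters, 2 * d, 2)) / np.sqrt(4 * d),
            name="encoder.w", block="encoder"))
        self.e_b = self.register(nn.Parameter(np.zeros(cfg.encoder_filters),
                                              name="encoder.b", block="encoder"))
        self.backbone_frozen = False

    # -- freezing policy ---------------------------------------------------
    def freeze_for_increment(self) -> None:
        """Freeze everything except the convolutional encoder (idempotent)."""
        self.set_trainable(False, blocks=set(BACKBONE_BLOCKS))
        self.backbone_frozen = True

    def unfreeze_all(self) -> None:
        self.set_trainable(True)
        self.backbone_frozen = False

    def _bn_training(self) -> bool:
        return self.training and not self.backbone_frozen

    # -- forward -----------------------------------------------------------
    def pre_encoder(self, x: np.ndarray) -> nn.Tensor:
        """Dual-branch feature map (N, 2*d_model, 1, T'), the encoder input."""
        cfg = self.cfg
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3 or x.shape[1] != cfg.n_channels:
            raise ValueError("expected (trials, channels, samples) with matching channels")
        if x.shape[-1] < max(cfg.temporal_kernels):
            raise ValueError("time axis shorter than the largest temporal kernel")
        bn_mode = self._bn_training()
        t = nn.Tensor(x[:, None, :, :])  # (N, 1, C, V)
        maps = []
        for (w, b), bn in zip(self.t_convs, self.t_bns):
            bn.training = bn_mode
            maps.append(bn(F.conv_time(t, w, b, same=True)))
        z = nn.concatenate(maps, axis=1)  # (N, S*f, C, V)
        self.s_bn.training = bn_mode
        z = self.s_bn(F.depthwise_spatial_conv(z, self.s_w, self.s_b)).elu()
        # dual pooling along time
        branches = []
        for pool, blocks in ((F.avg_pool_time, self.mhsa_avg), (F.var_pool_time, self.mhsa_var)):
            p = pool(z, cfg.pool_kernel, cfg.pool_stride)  # (N, F, 1, T')
            n, fm, _, tp = p.shape
            tok = p.reshape(n, fm, tp).transpose(0, 2, 1)  # tokens = time positions
            for blk in blocks:
                tok = blk(tok)
            branches.append(tok.transpose(0, 2, 1).reshape(n, fm, 1, tp))
        return nn.concatenate(branches, axis=1)  # (N, 2F, 1, T')

    def encode(self, pre: nn.Tensor) -> nn.Tensor:
        """Convolutional encoder + flatten: (N, 2F, 1, T') -> (N, d_tsf)."""
        out = F.conv_time(pre, self.e_w, self.e_b, same=False).elu()
        n = out.shape[0]
        return out.reshape(n, -1)

    def __call__(self, x: np.ndarray) -> nn.Tensor:
        return self.encode(self.pre_encoder(x))

    def recalibrate_bn(self, x: np.ndarray) -> None:
        """Set batch-norm statistics to the exact full-batch statistics of
        `x` under the current weights (running EMAs lag when the weights are
        still moving, which skews eval-mode features)."""
        if self.backbone_frozen:
            return
        bns = self.t_bns + [self.s_bn]
        saved = [bn.momentum for bn in bns]
        for bn in bns:
            bn.momentum = 1.0
        was = self.training
        self.train(True)
        self.pre_encoder(np.asarray(x, dtype=np.float64))
        for bn, m in zip(bns, saved):
            bn.momentum = m
        self.train(was)

    def extract(self, epochs: EEGEpochs | np.ndarray) -> np.ndarray:
        """Deterministic feature extraction (eval mode, no graph)."""
        x = epochs.data if isinstance(epochs, EEGEpochs) else epochs
        was = self.training
        self.eval()
        out = self(x).data.copy()
        self.train(was)
        return out


def block_digest(model: nn.Module, blocks=BACKBONE_BLOCKS) -> str:
    """SHA-256 digest of all parameters in the named blocks."""
    h = hashlib.sha256()
    for p in model.parameters():
        if p.block in blocks:
            h.update(p.name.encode())
            h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()


def _config_hash(cfg: MTSFEConfig) -> str:
    return hashlib.sha256(json.dumps(asdict(cfg), sort_keys=True).encode()).hexdigest()


def save_checkpoint(model: MTSFE, path: str) -> None:
    arrays = model.state_dict()
    bns = [bn for bn in model.t_bns] + [model.s_bn]
    for i, bn in enumerate(bns):
        arrays[f"__bn{i}_mean"] = bn.running_mean
        arrays[f"__bn{i}_var"] = bn.running_var
    np.savez(path, __config=json.dumps(asdict(model.cfg)),
             __hash=_config_hash(model.cfg), **arrays)


def load_checkpoint(path: str, cfg: MTSFEConfig) -> MTSFE:
    with np.load(path, allow_pickle=False) as f:
        if str(f["__hash"]) != _config_hash(cfg):
            raise ValueError("checkpoint was written with a different configuration")
        arrays = {k: f[k] for k in f.files if not k.startswith("__")}
        bn_state = {k: f[k] for k in f.files if k.startswith("__bn")}
    model = MTSFE(cfg)
    model.load_state_dict(arrays)
    bns = [bn for bn in model.t_bns] + [model.s_bn]
    for i, bn in enumerate(bns):
        bn.running_mean = bn_state[f"__bn{i}_mean"].copy()
        bn.running_var = bn_state[f"__bn{i}_var"].copy()
    return model
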