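"""Layers built on the autodiff core.

Initialization is fan-in uniform (Kaiming-style bounds) drawn from an
explicit ``numpy.random.Generator`` so that every network in the package
is bit-reproducible under a seed.
"""

from __future__ import annotations

import numpy as np

from .tensor import Parameter, Tensor, concatenate

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "BatchNorm2d",
    "Embedding",
    "MHSABlock",
]


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Tiny module base: parameter registry plus train/eval mode."""

    def __init__(self):
        self._params: list[Parameter] = []
        self._modules: list[Module] = []
        self.training = True

    def register(self, param: Parameter) -> Parameter:
        self._params.append(param)
        return param

    def add_module(self, mod: "Module") -> "Module":
        self._modules.append(mod)
        return mod

    def parameters(self) -> list[Parameter]:
        out = list(self._params)
        for m in self._modules:
            out.extend(m.parameters())
        return out

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules:
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def set_trainable(self, flag: bool, blocks: set[str] | None = None) -> None:
        for p in self.parameters():
            if blocks is None or p.block in blocks:
                p.trainable = flag

    def state_dict(self) -> dict[str, np.ndarray]:
        d: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.parameters()):
            d[f"{i}:{p.block}:{p.name}"] = p.data.copy()
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(d) != len(params):
            raise ValueError("state dict does not match module parameters")
        for i, p in enumerate(params):
            key = f"{i}:{p.block}:{p.name}"
            if key not in d:
                raise KeyError(f"missing parameter {key}")
            if d[key].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {key}")
            p.data = d[key].astype(np.float64).copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, block: str = "", name: str = "linear"):
        super().__init__()
        self.w = self.register(Parameter(_fan_in_uniform(rng, (n_in, n_out), n_in), name=f"{name}.w", block=block))
        self.b = self.register(Parameter(np.zeros(n_out), name=f"{name}.b", block=block))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, block: str = "", name: str = "ln", eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.g = self.register(Parameter(np.ones(dim), name=f"{name}.g", block=block))
        self.b = self.register(Parameter(np.zeros(dim), name=f"{name}.b", block=block))

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.g + self.b


class BatchNorm2d(Module):
    """Per-feature-map batch norm over (N, ·, ·) for maps shaped (N, F, C, V)."""

    def __init__(self, n_maps: int, block: str = "", name: str = "bn", eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.g = self.register(Parameter(np.ones(n_maps), name=f"{name}.g", block=block))
        self.b = self.register(Parameter(np.zeros(n_maps), name=f"{name}.b", block=block))
        self.running_mean = np.zeros(n_maps)
        self.running_var = np.ones(n_maps)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mu = Tensor(self.running_mean[None, :, None, None])
            var = Tensor(self.running_var[None, :, None, None])
            xc = x - mu
        gam = self.g.reshape(1, -1, 1, 1)
        bet = self.b.reshape(1, -1, 1, 1)
        return xc * (var + self.eps) ** -0.5 * gam + bet


class Embedding(Module):
    def __init__(self, n: int, dim: int, rng: np.random.Generator, block: str = "", name: str = "emb"):
        super().__init__()
        self.table = self.register(Parameter(rng.normal(0, 0.1, size=(n, dim)), name=f"{name}.table", block=block))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.table[np.asarray(idx, dtype=int)]

    def grow(self, n_new: int, rng: np.random.Generator) -> None:
        extra = rng.normal(0, 0.1, size=(n_new, self.table.shape[1]))
        self.table.data = np.concatenate([self.table.data, extra], axis=0)


class MHSABlock(Module):
    """Pre-norm transformer block: ``O = F + MHA(LN(F))`` then an MLP residual.

    Per-head attention is ``softmax(Q Kᵀ / sqrt(d_h)) V``; the h heads are
    concatenated and mapped back to the token width by a final projection.
    The terminal two-layer perceptron uses a configurable expansion (×2 by
    default) with ELU.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator, block: str = "",
                 name: str = "mhsa", mlp_expansion: int = 2):
        super().__init__()
        if d_model % n_heads:
            raise ValueError(f"token width {d_model} not divisible by {n_heads} heads")
        self.h = n_heads
        self.dh = d_model // n_heads
        self.ln1 = self.add_module(LayerNorm(d_model, block=block, name=f"{name}.ln1"))
        self.wq = self.add_module(Linear(d_model, d_model, rng, block=block, name=f"{name}.wq"))
        self.wk = self.add_module(Linear(d_model, d_model, rng, block=block, name=f"{name}.wk"))
        self.wv = self.add_module(Linear(d_model, d_model, rng, block=block, name=f"{name}.wv"))
        self.wo = self.add_module(Linear(d_model, d_model, rng, block=block, name=f"{name}.wo"))
        self.ln2 = self.add_module(LayerNorm(d_model, block=block, name=f"{name}.ln2"))
        self.mlp1 = self.add_module(Linear(d_model, mlp_expansion * d_model, rng, block=block, name=f"{name}.mlp1"))
        self.mlp2 = self.add_module(Linear(mlp_expansion * d_model, d_model, rng, block=block, name=f"{name}.mlp2"))

    def attention_weights(self, x: Tensor) -> np.ndarray:
        """Row-stochastic attention maps, shape (N, h, T, T). Diagnostic only."""
        _, attn = self._mha(self.ln1(x), return_attn=True)
        return attn

    def _mha(self, x: Tensor, return_attn: bool = False):
        n, t, d = x.shape
        q = self.wq(x).reshape(n, t, self.h, self.dh).transpose(0, 2, 1, 3)
        k = self.wk(x).reshape(n, t, self.h, self.dh).transpose(0, 2, 1, 3)
        v = self.wv(x).reshape(n, t, self.h, self.dh).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.dh))
        attn = scores.softmax(axis=-1)
        heads = attn @ v  # (N, h, T, dh)
        merged = heads.transpose(0, 2, 1, 3).reshape(n, t, d)
        out = self.wo(merged)
        if return_attn:
            return out, attn.data
        return out, None

    def __call__(self, x: Tensor) -> Tensor:
        mha, _ = self._mha(self.ln1(x))
        o = x + mha
        return o + self.mlp2(self.mlp1(self.ln2(o)).elu())
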