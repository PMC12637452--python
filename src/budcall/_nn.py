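"""Transformer building blocks and training utilities on the autodiff engine.

Pre-norm vision-transformer blocks (multi-head self-attention + GELU MLP),
a parameter/module registry with flat state dicts, and AdamW with decoupled
weight decay. Weight matrices carry weight decay; biases, layer-norm gains
and learnable tokens do not.
"""

from __future__ import annotations

import math

import numpy as np

from ._tensor import Tensor, layer_norm

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "MultiHeadAttention",
    "Mlp",
    "Block",
    "TransformerStack",
    "AdamW",
    "ema_update_",
]


class Module:
    """Tiny module system: registers parameters and sub-modules by attribute."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(
                f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}"
            )
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: "
                    f"{p.data.shape} vs {state[name].shape}"
                )
            p.data = state[name].astype(p.data.dtype).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _param(rng: np.random.Generator, *shape, std: float = 0.02) -> Tensor:
    return Tensor(
        (rng.standard_normal(shape) * std).astype(np.float32), requires_grad=True
    )


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        std = math.sqrt(2.0 / (d_in + d_out))
        self.weight = _param(rng, d_in, d_out, std=std)
        self.bias = Tensor(np.zeros(d_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int):
        super().__init__()
        self.gamma = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class MultiHeadAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by n_heads {n_heads}")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        h, hd = self.n_heads, self.head_dim
        qkv = self.qkv(x).reshape(b, t, 3, h, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # each (b, h, t, hd)
        attn = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(hd))
        attn = attn.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, d)
        return self.proj(out)


class Mlp(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class Block(Module):
    """Pre-norm transformer block: x + MHA(LN(x)); x + MLP(LN(x))."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 mlp_ratio: float = 4.0):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * mlp_ratio), rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.mlp(self.norm2(x))


class TransformerStack(Module):
    """Embedding-space transformer: blocks + final layer norm."""

    def __init__(self, dim: int, depth: int, n_heads: int,
                 rng: np.random.Generator, mlp_ratio: float = 4.0):
        super().__init__()
        self.blocks = [Block(dim, n_heads, rng, mlp_ratio) for _ in range(depth)]
        self.norm = LayerNorm(dim)

    def __call__(self, x: Tensor) -> Tensor:
        for blk in self.blocks:
            x = blk(x)
        return self.norm(x)


def _decays(name: str, param: Tensor) -> bool:
    # weight matrices decay; biases, norm gains/offsets, tokens do not
    return param.data.ndim >= 2 and name.endswith("weight")


class AdamW:
    """Adam with decoupled weight decay on flat (name, parameter) lists."""

    def __init__(self, named_params, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(named_params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {n: np.zeros_like(p.data) for n, p in self.params}
        self.v = {n: np.zeros_like(p.data) for n, p in self.params}

    def zero_grad(self) -> None:
        for _, p in self.params:
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        if lr is None:
            lr = self.lr
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for name, p in self.params:
            g = p.grad
            if g is None:
                continue
            m = self.m[name]
            v = self.v[name]
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and _decays(name, p):
                update = update + self.weight_decay * p.data
            p.data = p.data - lr * update


def ema_update_(shadow: dict[str, np.ndarray], live: dict[str, np.ndarray],
                decay: float) -> None:
    """In-place shadow <- decay * shadow + (1 - decay) * live."""
    if set(shadow) != set(live):
        raise ValueError("EMA shadow/live parameter names differ")
    for name, s in shadow.items():
        if s.shape != live[name].shape:
            raise ValueError(f"EMA shape mismatch for {name}")
        s *= decay
        s += (1.0 - decay) * live[name]
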