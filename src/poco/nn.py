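"""Network building blocks: linear layers, layer norm, rotary multi-head
attention and pre-norm residual attention blocks, on top of the autodiff
engine in :mod:`poco.autodiff`.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor, as_tensor, concat


class Module:
    """Lightweight parameter container with automatic recursive discovery."""

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.named_parameters(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        out[f"{key}.{i}"] = item
        return out

    def parameters(self) -> list[Parameter]:
        return list(self.named_parameters().values())

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 zero_init: bool = False, bias_init: float = 0.0):
        if zero_init:
            w = np.zeros((out_dim, in_dim))
        else:
            w = rng.normal(0.0, 1.0 / np.sqrt(in_dim), size=(out_dim, in_dim))
        self.weight = Parameter(w)
        self.bias = Parameter(np.full(out_dim, bias_init, dtype=np.float64))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight.transpose(1, 0) + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self._eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self._eps) ** -0.5 * self.gamma + self.beta


def rotary_angles(timestamps, head_dim: int, base: float = 10000.0):
    """cos/sin tables for rotary position embedding.

    ``timestamps`` may be a plain array (fixed token times) or a Tensor
    (learned latent positions); the result is a (L, head_dim) pair using the
    half-rotation convention.
    """
    half = head_dim // 2
    inv_freq = base ** (-np.arange(half) / half)
    t = as_tensor(timestamps)
    angles = t.reshape(-1, 1) * Tensor(inv_freq.reshape(1, half))
    cos = concat([angles.cos(), angles.cos()], axis=-1)
    sin = concat([angles.sin(), angles.sin()], axis=-1)
    return cos, sin


def apply_rotary(x: Tensor, cos: Tensor, sin: Tensor) -> Tensor:
    """Rotate query/key vectors; x has shape (..., L, head_dim)."""
    half = x.shape[-1] // 2
    x1 = x[..., :half]
    x2 = x[..., half:]
    rotated = concat([-x2, x1], axis=-1)
    return x * cos + rotated * sin


class MultiheadAttention(Module):
    """Multi-head scaled dot-product attention with optional rotary times."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 rotary: bool = True):
        if dim % heads != 0:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        if rotary and (dim // heads) % 2 != 0:
            raise ValueError("head dim must be even for rotary embedding")
        self.q_proj = Linear(dim, dim, rng)
        self.k_proj = Linear(dim, dim, rng)
        self.v_proj = Linear(dim, dim, rng)
        self.out_proj = Linear(dim, dim, rng)
        self._heads = heads
        self._dim = dim
        self._rotary = rotary

    def _split(self, x: Tensor, length: int) -> Tensor:
        b = x.shape[0]
        return x.reshape(b, length, self._heads, self._dim // self._heads) \
                .transpose(0, 2, 1, 3)

    def __call__(self, q_in: Tensor, kv_in: Tensor, t_q=None, t_k=None) -> Tensor:
        lq, lk = q_in.shape[-2], kv_in.shape[-2]
        dh = self._dim // self._heads
        q = self._split(self.q_proj(q_in), lq)
        k = self._split(self.k_proj(kv_in), lk)
        v = self._split(self.v_proj(kv_in), lk)
        if self._rotary and t_q is not None:
            q = apply_rotary(q, *rotary_angles(t_q, dh))
        if self._rotary and t_k is not None:
            k = apply_rotary(k, *rotary_angles(t_k, dh))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = scores.softmax(axis=-1)
        out = attn @ v                                  # (B, H, Lq, dh)
        b = out.shape[0]
        out = out.transpose(0, 2, 1, 3).reshape(b, lq, self._dim)
        return self.out_proj(out)


class AttentionBlock(Module):
    """Pre-norm residual attention block with a small gated-free MLP.

    Used for both cross-attention (queries differ from keys/values) and
    latent self-attention, Perceiver-IO style.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 rotary: bool = True, ffn_mult: int = 2):
        self.norm_q = LayerNorm(dim)
        self.norm_kv = LayerNorm(dim)
        self.attn = MultiheadAttention(dim, heads, rng, rotary=rotary)
        self.norm_ffn = LayerNorm(dim)
        self.ffn_in = Linear(dim, ffn_mult * dim, rng)
        self.ffn_out = Linear(ffn_mult * dim, dim, rng)

    def __call__(self, x_q: Tensor, x_kv: Tensor | None = None,
                 t_q=None, t_k=None) -> Tensor:
        kv = x_q if x_kv is None else x_kv
        h = x_q + self.attn(self.norm_q(x_q), self.norm_kv(kv), t_q=t_q, t_k=t_k)
        return h + self.ffn_out(self.ffn_in(self.norm_ffn(h)).gelu())
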