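"""Dual-attention U-shaped transformer for nucleus segmentation.

The network is a U-Net-like pure-transformer segmenter.  An overlapping
patch embedding (7x7 dense projection, stride 4) tokenizes the RGB tile
at quarter resolution.  The encoder stacks Dual Transformer blocks —
each applies linear-complexity *efficient attention* over tokens
(spatial) followed by *transposed attention* over channels
(cross-covariance, d x d) — with 2x2 patch merging between stages
(resolution /2, channels x2).  A two-block bottleneck sits at 1/16
resolution.  The decoder mirrors the encoder with patch expanding
(resolution x2, channels /2) and fuses each skip with a cross-attention
module (SCA) in which the encoder tokens act as queries against
keys/values projected from the decoder stream.  A final 4x expansion and
a linear projection yield per-pixel class scores at input resolution.

Both attention operators avoid the N x N token-affinity matrix entirely:
efficient attention contracts keys with values first (a d x d global
context), transposed attention works on the d x d channel cross-
covariance, so cost is linear in token count.

Training minimizes ``0.6 * soft-Dice loss + 0.4 * BCE`` on the
foreground (nucleus) probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Parameter, SGD, Tensor, as_tensor  # noqa: F401  (SGD re-export)

__all__ = [
    "ModelSpec",
    "LossWeights",
    "Module",
    "Linear",
    "efficient_attention",
    "transposed_attention",
    "standard_attention",
    "sca_attention",
    "EfficientAttention",
    "TransposedAttention",
    "MixFFN",
    "DualTransformerBlock",
    "PatchEmbed",
    "PatchMerging",
    "PatchExpanding",
    "SCAFusion",
    "NucleusSegmenter",
    "composite_loss",
    "combine_loss",
    "dice_loss",
    "bce_with_logits",
    "count_parameters",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------
@dataclass
class ModelSpec:
    """Architecture configuration.

    ``base_dim`` is the token width C at the first (1/4-resolution)
    stage; stage i runs at C * 2**i.  ``stage_depths`` counts Dual
    Transformer blocks per encoder stage (the decoder mirrors it); the
    bottleneck always uses two blocks.  ``heads_per_stage`` splits both
    attentions into heads.  The patch embedding must keep its stride of
    4 (the tokenizer reduces resolution by exactly that factor).
    """

    in_channels: int = 3
    num_classes: int = 2
    base_dim: int = 64
    stage_depths: tuple = (2, 2, 2)
    heads_per_stage: tuple = (1, 2, 4)
    patch_kernel: int = 7
    patch_stride: int = 4
    patch_padding: int = 3
    ffn_expansion: int = 4
    temperature_init: float = 1.0
    dropout: float = 0.0
    seed: int = 42

    def __post_init__(self):
        if self.patch_stride != 4:
            raise ValueError("patch embedding stride must be 4")
        if len(self.stage_depths) != len(self.heads_per_stage):
            raise ValueError("stage_depths and heads_per_stage must have equal length")
        if self.base_dim % 4 != 0:
            raise ValueError("base_dim must be divisible by 4 (final 4x expansion)")
        for i, h in enumerate(self.heads_per_stage):
            if (self.base_dim * 2 ** i) % h != 0:
                raise ValueError(f"stage {i} dim not divisible by its head count")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")

    @classmethod
    def tiny(cls, **kw) -> "ModelSpec":
        """Desk-scale spec used throughout the test suite."""
        kw.setdefault("base_dim", 16)
        return cls(**kw)

    def to_json(self) -> str:
        d = asdict(self)
        d["stage_depths"] = list(self.stage_depths)
        d["heads_per_stage"] = list(self.heads_per_stage)
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        d = json.loads(s)
        d["stage_depths"] = tuple(d["stage_depths"])
        d["heads_per_stage"] = tuple(d["heads_per_stage"])
        return cls(**d)


@dataclass
class LossWeights:
    """Composite-loss weights: total = dice_weight*Dice + bce_weight*BCE."""

    dice_weight: float = 0.6
    bce_weight: float = 0.4
    dice_smoothing: float = 1.0

    def __post_init__(self):
        if abs(self.dice_weight + self.bce_weight - 1.0) > 1e-9:
            raise ValueError("dice_weight + bce_weight must equal 1")
        if self.dice_smoothing <= 0:
            raise ValueError("dice_smoothing must be positive")


# --------------------------------------------------------------------------
# functional attention operators (single-head; broadcast over leading axes)
# --------------------------------------------------------------------------
def _check_finite(*tensors):
    for t in tensors:
        if not np.isfinite(t.data).all():
            raise ValueError("attention inputs contain NaN or Inf")


def efficient_attention(q, k, v) -> Tensor:
    """Linear-complexity attention: ``rho_q(Q) @ (rho_k(K)^T @ V)``.

    ``rho_q`` is a softmax over the channel axis (each token's query is
    a convex weight vector) and ``rho_k`` a softmax over the token axis
    (each key channel is a convex weight over tokens).  The key-value
    contraction forms a d_k x d_v global context first, so no N x N
    matrix is ever materialized.
    """
    q, k, v = as_tensor(q), as_tensor(k), as_tensor(v)
    _check_finite(q, k, v)
    rho_q = q.softmax(axis=-1)
    rho_k = k.softmax(axis=-2)
    context = rho_k.swapaxes(-1, -2) @ v  # (d_k, d_v)
    return rho_q @ context


def transposed_attention(q, k, v, tau) -> Tensor:
    """Channel (cross-covariance) attention: ``V @ softmax(K^T Q / tau)``.

    Queries and keys are L2-normalized per channel column (over the
    token axis); the d_k x d_q attention map is softmax-normalized over
    its key-channel axis, so each output channel is a convex mix of
    value channels.  Cost is quadratic in d, linear in N.
    """
    q, k, v = as_tensor(q), as_tensor(k), as_tensor(v)
    _check_finite(q, k, v)
    tau_t = as_tensor(tau)
    if np.any(tau_t.data <= 0):
        raise ValueError("temperature tau must be positive")
    qn = q / ((q * q).sum(axis=-2, keepdims=True) + 1e-12).sqrt()
    kn = k / ((k * k).sum(axis=-2, keepdims=True) + 1e-12).sqrt()
    ct = (kn.swapaxes(-1, -2) @ qn) / tau_t
    ct = ct.softmax(axis=-2)
    return v @ ct


def standard_attention(q, k, v, bias=None) -> Tensor:
    """Quadratic softmax attention (reference implementation only).

    ``softmax(Q K^T / sqrt(d) + B) V`` with an optional additive bias B
    broadcastable to N x N.  Used as a test oracle; the network itself
    never materializes the N x N map.
    """
    q, k, v = as_tensor(q), as_tensor(k), as_tensor(v)
    d = q.shape[-1]
    logits = (q @ k.swapaxes(-1, -2)) / np.sqrt(d)
    if bias is not None:
        logits = logits + as_tensor(bias)
    return logits.softmax(axis=-1) @ v


def sca_attention(q, k, v) -> Tensor:
    """Skip-fusion attention: ``rho_v(V) @ (rho_k(K)^T @ Q)``.

    Same axis convention as :func:`efficient_attention`: ``rho_k`` and
    ``rho_v`` normalize over the token axis, the context ``rho_k(K)^T Q``
    is d x d, and the value mixing is convex over tokens.
    """
    q, k, v = as_tensor(q), as_tensor(k), as_tensor(v)
    _check_finite(q, k, v)
    rho_v = v.softmax(axis=-2)
    rho_k = k.softmax(axis=-2)
    context = rho_k.swapaxes(-1, -2) @ q
    return rho_v @ context


# --------------------------------------------------------------------------
# module system
# --------------------------------------------------------------------------
class Module:
    """Tiny parameter-registry base class (insertion-ordered)."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        mine = dict(self.named_parameters())
        if set(mine) != set(state):
            missing = set(mine) ^ set(state)
            raise ValueError(f"state dict mismatch: {sorted(missing)}")
        for name, p in mine.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.array(state[name], dtype=np.float64)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, scale: float = 1.0):
        if scale == 0.0:
            self.weight = Parameter(np.zeros((d_in, d_out)))
        else:
            std = scale * np.sqrt(2.0 / (d_in + d_out))
            self.weight = Parameter(rng.normal(0.0, std, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self._eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self._eps).sqrt() * self.gamma + self.beta


class DepthwiseConv3x3(Module):
    """3x3 depthwise convolution on a (B, h, w, d) token grid."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, np.sqrt(1.0 / 9.0), size=(9, dim)))
        self.bias = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        u = x.unfold2d(3, 1, 1)  # (B, h, w, 9, d)
        return (u * self.weight).sum(axis=3) + self.bias


class MixFFN(Module):
    """Feed-forward with implicit positional mixing:
    ``FC(GELU(DWConv(FC(x))))`` on the grid layout."""

    def __init__(self, dim: int, expansion: int, rng: np.random.Generator):
        hidden = dim * expansion
        self.fc1 = Linear(dim, hidden, rng)
        self.dwconv = DepthwiseConv3x3(hidden, rng)
        # zero-init output projection: the residual branch starts silent,
        # which keeps the deep post-residual stack stable at the published
        # (large) base learning rate
        self.fc2 = Linear(hidden, dim, rng, scale=0.0)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.dwconv(self.fc1(x)).gelu())


def _split_heads(x: Tensor, heads: int) -> Tensor:
    b, n, d = x.shape
    return x.reshape(b, n, heads, d // heads).transpose(0, 2, 1, 3)


def _merge_heads(x: Tensor) -> Tensor:
    b, h, n, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, n, h * dh)


class EfficientAttention(Module):
    """Multi-head spatial attention with linear token complexity."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        self.heads = heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng, scale=0.0)  # silent residual branch at init

    def __call__(self, x: Tensor) -> Tensor:
        b, h, w, d = x.shape
        t = x.reshape(b, h * w, d)
        q = _split_heads(self.wq(t), self.heads)
        k = _split_heads(self.wk(t), self.heads)
        v = _split_heads(self.wv(t), self.heads)
        out = _merge_heads(efficient_attention(q, k, v))
        return self.wo(out).reshape(b, h, w, d)


class TransposedAttention(Module):
    """Multi-head channel attention with a learnable temperature per head.

    The temperature is stored as its logarithm so it stays positive.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator, tau_init: float = 1.0):
        if tau_init <= 0:
            raise ValueError("temperature must be positive")
        self.heads = heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng, scale=0.0)  # silent residual branch at init
        self.log_tau = Parameter(np.full((heads, 1, 1), np.log(tau_init)))

    def __call__(self, x: Tensor) -> Tensor:
        b, h, w, d = x.shape
        t = x.reshape(b, h * w, d)
        q = _split_heads(self.wq(t), self.heads)
        k = _split_heads(self.wk(t), self.heads)
        v = _split_heads(self.wv(t), self.heads)
        tau = self.log_tau.exp()
        out = _merge_heads(transposed_attention(q, k, v, tau))
        return self.wo(out).reshape(b, h, w, d)


class DualTransformerBlock(Module):
    """Efficient (spatial) then transposed (channel) attention, each
    followed by a norm + Mix-FFN residual sub-block; post-residual
    structure, shape preserving."""

    def __init__(self, dim: int, heads: int, expansion: int, rng: np.random.Generator,
                 tau_init: float = 1.0):
        self.attn_spatial = EfficientAttention(dim, heads, rng)
        self.norm1 = LayerNorm(dim)
        self.ffn1 = MixFFN(dim, expansion, rng)
        self.attn_channel = TransposedAttention(dim, heads, rng, tau_init)
        self.norm2 = LayerNorm(dim)
        self.ffn2 = MixFFN(dim, expansion, rng)

    def __call__(self, x: Tensor) -> Tensor:
        y = self.attn_spatial(x) + x
        y = self.ffn1(self.norm1(y)) + y
        z = self.attn_channel(y) + y
        return self.ffn2(self.norm2(z)) + z


class PatchEmbed(Module):
    """Overlapping patch embedding: 7x7 neighborhoods, stride 4, pad 3."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        k = spec.patch_kernel
        self._k, self._s, self._p = k, spec.patch_stride, spec.patch_padding
        self.proj = Linear(k * k * spec.in_channels, spec.base_dim, rng)

    def __call__(self, img: Tensor) -> Tensor:
        b, h, w, c = img.shape
        u = img.unfold2d(self._k, self._s, self._p)  # (B, h/4, w/4, k*k, c)
        bo, ho, wo, kk, _ = u.shape
        return self.proj(u.reshape(bo, ho, wo, kk * c))


class PatchMerging(Module):
    """2x2 token aggregation: (h, w, d) -> (h/2, w/2, 2d)."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.reduction = Linear(4 * dim, 2 * dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        b, h, w, d = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"grid dims must be even for merging, got {(h, w)}")
        x = x.reshape(b, h // 2, 2, w // 2, 2, d)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(b, h // 2, w // 2, 4 * d)
        return self.reduction(x)


class PatchExpanding(Module):
    """2x upsampling: (h, w, d) -> (2h, 2w, d/2) via linear expansion to
    2d and a pixel-shuffle reshape."""

    def __init__(self, dim: int, rng: np.random.Generator):
        if dim % 2:
            raise ValueError("dim must be divisible by 2 for expanding")
        self.expand = Linear(dim, 2 * dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        b, h, w, d = x.shape
        t = self.expand(x)  # (b, h, w, 2d)
        t = t.reshape(b, h, w, 2, 2, d // 2)
        return t.transpose(0, 1, 3, 2, 4, 5).reshape(b, 2 * h, 2 * w, d // 2)


class FinalExpanding(Module):
    """4x upsampling back to pixel resolution: (h, w, d) -> (4h, 4w, d/4)."""

    def __init__(self, dim: int, rng: np.random.Generator):
        if dim % 4:
            raise ValueError("dim must be divisible by 4 for the final expansion")
        self.expand = Linear(dim, 4 * dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        b, h, w, d = x.shape
        t = self.expand(x)  # (b, h, w, 4d)
        t = t.reshape(b, h, w, 4, 4, d // 4)
        return t.transpose(0, 1, 3, 2, 4, 5).reshape(b, 4 * h, 4 * w, d // 4)


class SCAFusion(Module):
    """Skip Connection Attention: encoder tokens query a context built
    from keys/values projected off the decoder stream (after a linear
    rescale of the decoder tokens to the encoder width).

    The module output adds the attention message to both streams
    (``x1' + x2 + E``): the skip exists to hand the decoder the
    encoder's spatial detail, and the additive fusion keeps per-token
    information flowing from the first step while the global attention
    message is learned.
    """

    def __init__(self, dim_decoder: int, dim_encoder: int, rng: np.random.Generator):
        self.fc = Linear(dim_decoder, dim_encoder, rng)
        self.proj_k = Linear(dim_encoder, dim_encoder, rng)
        self.proj_v = Linear(dim_encoder, dim_encoder, rng)
        self.proj_q = Linear(dim_encoder, dim_encoder, rng)

    def __call__(self, x1_decoder: Tensor, x2_encoder: Tensor) -> Tensor:
        b1, h1, w1, _ = x1_decoder.shape
        b2, h2, w2, d2 = x2_encoder.shape
        if (b1, h1, w1) != (b2, h2, w2):
            raise ValueError(
                f"incompatible grids: decoder {x1_decoder.shape} vs encoder {x2_encoder.shape}"
            )
        x1p = self.fc(x1_decoder).reshape(b1, h1 * w1, d2)
        k = self.proj_k(x1p)
        v = self.proj_v(x1p)
        x2_t = x2_encoder.reshape(b2, h2 * w2, d2)
        q = self.proj_q(x2_t)
        e = sca_attention(q, k, v)
        return (x1p + x2_t + e).reshape(b2, h2, w2, d2)


class NucleusSegmenter(Module):
    """The full U-shaped dual-attention segmentation network."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        self.spec_obj = spec  # not a Parameter; excluded from the registry walk
        n_stages = len(spec.stage_depths)
        dims = [spec.base_dim * 2 ** i for i in range(n_stages)]
        tau = spec.temperature_init
        ex = spec.ffn_expansion

        self.patch_embed = PatchEmbed(spec, rng)
        self.enc_stages = [
            [DualTransformerBlock(dims[i], spec.heads_per_stage[i], ex, rng, tau)
             for _ in range(spec.stage_depths[i])]
            for i in range(n_stages)
        ]
        self.merges = [PatchMerging(dims[i], rng) for i in range(n_stages - 1)]
        self.bottleneck = [
            DualTransformerBlock(dims[-1], spec.heads_per_stage[-1], ex, rng, tau)
            for _ in range(2)
        ]
        # decoder: mirror stages n-2 .. 0
        self.expands = [PatchExpanding(dims[i + 1], rng) for i in reversed(range(n_stages - 1))]
        self.scas = [SCAFusion(dims[i], dims[i], rng) for i in reversed(range(n_stages - 1))]
        self.dec_stages = [
            [DualTransformerBlock(dims[i], spec.heads_per_stage[i], ex, rng, tau)
             for _ in range(spec.stage_depths[i])]
            for i in reversed(range(n_stages - 1))
        ]
        self.final_expand = FinalExpanding(dims[0], rng)
        self.head = Linear(dims[0] // 4, spec.num_classes, rng)

    # parameter walker must skip the spec dataclass
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if name == "spec_obj":
                continue
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, (list, tuple)):
                        for j, sub in enumerate(item):
                            if isinstance(sub, Module):
                                yield from sub.named_parameters(f"{full}.{i}.{j}.")

    def __call__(self, img) -> Tensor:
        """Per-pixel class scores of shape (B, H, W, num_classes)."""
        x = as_tensor(img)
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        b, h, w, c = x.shape
        if h % 16 or w % 16:
            raise ValueError(
                f"input spatial dims must be divisible by 16, got {(h, w)}"
            )
        t = self.patch_embed(x)
        skips = []
        for i, stage in enumerate(self.enc_stages):
            for block in stage:
                t = block(t)
            if i < len(self.merges):
                skips.append(t)
                t = self.merges[i](t)
        for block in self.bottleneck:
            t = block(t)
        for expand, sca, stage, skip in zip(
            self.expands, self.scas, self.dec_stages, reversed(skips)
        ):
            t = expand(t)
            t = sca(t, skip)
            for block in stage:
                t = block(t)
        t = self.final_expand(t)
        return self.head(t)

    def predict_proba(self, img: np.ndarray) -> np.ndarray:
        """Foreground (nucleus) probability map as a numpy array."""
        scores = self(img)
        z = scores.data[..., 1] - scores.data[..., 0]
        p = 0.5 * (1.0 + np.tanh(0.5 * z))
        return p[0] if np.asarray(img).ndim == 3 else p

    def predict_mask(self, img: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(img) >= threshold).astype(np.uint8)


# --------------------------------------------------------------------------
# loss
# --------------------------------------------------------------------------
_FG_MINUS_BG = np.array([[-1.0], [1.0]])


def _foreground_logit(scores: Tensor) -> Tensor:
    """Two-class scores -> single foreground logit (softmax-equivalent)."""
    z = scores @ _FG_MINUS_BG
    return z.reshape(z.shape[:-1])


def bce_with_logits(z: Tensor, target: np.ndarray) -> Tensor:
    """Numerically stable binary cross-entropy, mean over all pixels."""
    t = as_tensor(target)
    return (z.softplus() - z * t).mean()


def dice_loss(z: Tensor, target: np.ndarray, smoothing: float = 1.0) -> Tensor:
    """Soft Dice loss on foreground probabilities, averaged over the batch."""
    p = z.sigmoid()
    t = as_tensor(target)
    axes = tuple(range(1, p.ndim))
    inter = (p * t).sum(axis=axes)
    denom = p.sum(axis=axes) + t.sum(axis=axes)
    dice = (2.0 * inter + smoothing) / (denom + smoothing)
    return (1.0 - dice).mean()


def combine_loss(dice_value, bce_value, weights: LossWeights = LossWeights()):
    """The composite total: dice_weight*Dice + bce_weight*BCE."""
    return weights.dice_weight * dice_value + weights.bce_weight * bce_value


def composite_loss(scores: Tensor, mask: np.ndarray,
                   weights: LossWeights = LossWeights()) -> Tensor:
    """Composite segmentation loss on (B, H, W, 2) scores and a binary mask."""
    mask = np.asarray(mask)
    if mask.ndim == scores.ndim - 2:
        mask = mask[None, ...]
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must contain only 0/1 values")
    if mask.shape != scores.shape[:-1]:
        raise ValueError(f"mask shape {mask.shape} does not match scores {scores.shape}")
    z = _foreground_logit(scores)
    return combine_loss(
        dice_loss(z, mask, weights.dice_smoothing), bce_with_logits(z, mask), weights
    )


def count_parameters(spec: ModelSpec) -> int:
    """Number of trainable scalars for a given architecture spec."""
    model = NucleusSegmenter(spec, np.random.default_rng(0))
    return int(sum(p.data.size for p in model.parameters()))
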