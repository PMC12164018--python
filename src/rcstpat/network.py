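"""Residual-conditioned sparse transformer (RCST) restoration network.

The restoration map runs a U-shaped encoder–decoder of Sparse Transformer
Blocks (STB) twice.  Phase one produces a preliminary restoration
x1 = G(y); the transport residual r0 = y - x1 is the fingerprint of the
degradation (for sparse-view tomography: the streak field).  Phase two runs
the same generator again on y, with a pyramid encoding of r0 injected into
the bottleneck and every decoder level through gated cross-stage fusion.

Each STB replaces dense self-attention with top-k sparse channel attention
(TKSA): attention is computed over the C^ x C^ channel-transposed matrix
M = Q K^T / lambda, and per row only the k largest scores survive a masked
softmax; everything else gets probability exactly zero.  The feed-forward
half is a mixed-scale network (MSFN): a 1x1 expansion followed by parallel
3x3 and 5x5 depth-wise branches whose second stage cross-feeds the two
scales before a 1x1 fusion and residual add.

All tensors are (C, H, W) float64; initialization is fully determined by
``ModelConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .autodiff import Tensor, concat, masked_softmax
from .layers import (
    ChannelLayerNorm,
    Conv2d,
    Module,
    pixel_shuffle,
    pixel_unshuffle,
)

__all__ = [
    "ModelConfig",
    "top_k_mask",
    "TopKSparseAttention",
    "MixedScaleFFN",
    "SparseTransformerBlock",
    "Downsample",
    "Upsample",
    "ResidualEncoder",
    "ConditionFuse",
    "Generator",
    "RCST",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; every field is overridable.

    Defaults follow restoration-transformer practice: 4 pyramid levels with
    (2, 3, 3, 4) blocks, 48 base channels and (1, 2, 4, 8) heads.  The
    ``toy()`` preset (8 channels, 3 levels, 1 block per level) is what the
    desk-scale experiments and tests use.
    """

    base_channels: int = 48
    n_levels: int = 4
    stb_per_level: tuple[int, ...] = (2, 3, 3, 4)
    heads_per_level: tuple[int, ...] = (1, 2, 4, 8)
    topk_ratios: tuple[float, ...] = (1 / 2, 2 / 3, 3 / 4, 4 / 5)
    msfn_expansion: float = 2.0
    condition_gate_init: float = 0.1
    attention: str = "topk"  # "topk" | "dense" (ablation)
    ffn: str = "mixed"  # "mixed" | "single" (ablation)
    residual_conditioning: bool = True  # ablation toggle
    seed: int = 0

    def __post_init__(self):
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if len(self.stb_per_level) != self.n_levels:
            raise ValueError("stb_per_level must have n_levels entries")
        if len(self.heads_per_level) != self.n_levels:
            raise ValueError("heads_per_level must have n_levels entries")
        if not all(0.0 < r <= 1.0 for r in self.topk_ratios):
            raise ValueError("topk_ratios must lie in (0, 1]")
        for lvl, h in enumerate(self.heads_per_level):
            if self.channels_at(lvl) % h:
                raise ValueError(
                    f"level {lvl}: {self.channels_at(lvl)} channels not divisible "
                    f"by {h} heads"
                )
        if self.attention not in ("topk", "dense"):
            raise ValueError("attention must be 'topk' or 'dense'")
        if self.ffn not in ("mixed", "single"):
            raise ValueError("ffn must be 'mixed' or 'single'")

    def channels_at(self, level: int) -> int:
        return self.base_channels * (2**level)

    @staticmethod
    def toy(**overrides) -> "ModelConfig":
        base = dict(
            base_channels=8, n_levels=3, stb_per_level=(1, 1, 1),
            heads_per_level=(1, 2, 4),
        )
        base.update(overrides)
        return ModelConfig(**base)


def top_k_mask(M: np.ndarray, k: int) -> np.ndarray:
    """Binary mask retaining the k largest entries of each row (last axis).

    Ties are broken deterministically by the lowest column index, via a
    stable sort on the negated scores.
    """
    n = M.shape[-1]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range [1, {n}]")
    idx = np.argsort(-M, axis=-1, kind="stable")[..., :k]
    mask = np.zeros(M.shape, dtype=bool)
    np.put_along_axis(mask, idx, True, axis=-1)
    return mask


class TopKSparseAttention(Module):
    """Channel-transposed multi-head attention with per-row top-k sparsity.

    1x1 conv then 3x3 depth-wise conv produce Q, K, V; each head forms
    M = Q K^T / lambda over its C^ channels, keeps the top-k scores per row
    (k = ceil(ratio * C^), per-head ratio cycled from the config list), and
    applies a masked softmax.  ``k_ratio=1`` (or attention="dense") is exact
    dense attention.
    """

    def __init__(self, channels: int, heads: int, ratios: tuple[float, ...],
                 rng: np.random.Generator, dense: bool = False):
        if channels % heads:
            raise ValueError(f"{channels} channels not divisible by {heads} heads")
        self.heads = heads
        self.channels = channels
        self.head_ratios = tuple(
            1.0 if dense else ratios[h % len(ratios)] for h in range(heads)
        )
        self.qkv = Conv2d(channels, 3 * channels, 1, rng)
        self.qkv_dw = Conv2d(3 * channels, 3 * channels, 3, rng, groups=3 * channels)
        self.temperature = Tensor(np.ones((heads, 1, 1)), requires_grad=True)
        # zero-init output projection: the attention residual branch starts
        # inert and is grown by training
        self.proj = Conv2d(channels, channels, 1, rng, init="zero")

    def __call__(self, x: Tensor) -> Tensor:
        C, H, W = x.shape
        ch = C // self.heads
        qkv = self.qkv_dw(self.qkv(x))  # (3C, H, W)
        qkv = qkv.reshape(3, self.heads, ch, H * W)
        q, k, v = qkv[0], qkv[1], qkv[2]
        # cosine-similarity channel attention: L2-normalize each channel's
        # spatial profile so scores are scale- and image-size-free
        q = q / (((q * q).sum(axis=-1, keepdims=True) + 1e-12).sqrt())
        k = k / (((k * k).sum(axis=-1, keepdims=True) + 1e-12).sqrt())
        scores = (q @ k.transpose(0, 2, 1)) / self.temperature  # (heads, ch, ch)
        mask = np.ones(scores.shape, dtype=bool)
        for h, ratio in enumerate(self.head_ratios):
            k_h = int(np.ceil(ratio * ch))
            mask[h] = top_k_mask(scores.data[h], k_h)
        attn = masked_softmax(scores, mask)
        out = (attn @ v).reshape(C, H, W)
        return self.proj(out)


class MixedScaleFFN(Module):
    """Two-stage mixed-scale feed-forward network with a residual add.

    X^ = 1x1(x); p1 = ReLU(dw3(X^)); s1 = ReLU(dw5(X^));
    p2 = ReLU(dw3([p1, s1])); s2 = ReLU(dw5([s1, p1]));
    out = 1x1([p2, s2]) + x.  ``single_scale=True`` (ablation) keeps only
    the 3x3 branch: out = 1x1(ReLU(dw3(ReLU(dw3(X^))))) + x.

    Normalization is applied by the enclosing transformer block.
    """

    def __init__(self, channels: int, expansion: float, rng: np.random.Generator,
                 single_scale: bool = False):
        e = max(1, int(round(channels * expansion)))
        self.single_scale = single_scale
        self.expand = Conv2d(channels, e, 1, rng)
        self.dw3_1 = Conv2d(e, e, 3, rng, groups=e)
        # zero-init fusion: the feed-forward residual branch starts inert
        if single_scale:
            self.dw3_2 = Conv2d(e, e, 3, rng, groups=e)
            self.fuse = Conv2d(e, channels, 1, rng, init="zero")
        else:
            self.dw5_1 = Conv2d(e, e, 5, rng, groups=e)
            self.dw3_2 = Conv2d(2 * e, 2 * e, 3, rng, groups=2 * e)
            self.dw5_2 = Conv2d(2 * e, 2 * e, 5, rng, groups=2 * e)
            self.fuse = Conv2d(4 * e, channels, 1, rng, init="zero")

    def __call__(self, x: Tensor) -> Tensor:
        xh = self.expand(x)
        if self.single_scale:
            h = self.dw3_2(self.dw3_1(xh).relu()).relu()
            return self.fuse(h) + x
        p1 = self.dw3_1(xh).relu()
        s1 = self.dw5_1(xh).relu()
        p2 = self.dw3_2(concat([p1, s1], axis=0)).relu()
        s2 = self.dw5_2(concat([s1, p1], axis=0)).relu()
        return self.fuse(concat([p2, s2], axis=0)) + x


class SparseTransformerBlock(Module):
    """x' = x + TKSA(LN(x)); out = x' + MSFN(LN(x'))."""

    def __init__(self, channels: int, heads: int, cfg: ModelConfig,
                 rng: np.random.Generator):
        self.ln1 = ChannelLayerNorm(channels)
        self.attn = TopKSparseAttention(
            channels, heads, cfg.topk_ratios, rng, dense=(cfg.attention == "dense")
        )
        self.ln2 = ChannelLayerNorm(channels)
        self.ffn = MixedScaleFFN(
            channels, cfg.msfn_expansion, rng, single_scale=(cfg.ffn == "single")
        )

    def __call__(self, x: Tensor) -> Tensor:
        xp = x + self.attn(self.ln1(x))
        return xp + self.ffn(self.ln2(xp))


class Downsample(Module):
    """Pixel-unshuffle (C -> 4C, H/2) then 1x1 reduction to 2C."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.reduce = Conv2d(4 * channels, 2 * channels, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.reduce(pixel_unshuffle(x, 2))


class Upsample(Module):
    """1x1 expansion to 2C then pixel-shuffle (-> C/2, 2H)."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.expand = Conv2d(channels, 2 * channels, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return pixel_shuffle(self.expand(x), 2)


class ConditionFuse(Module):
    """out = feat + gate * proj(embed); per-channel learnable gate."""

    def __init__(self, channels: int, gate_init: float, rng: np.random.Generator):
        self.proj = Conv2d(channels, channels, 1, rng)
        self.gate = Tensor(np.full((channels, 1, 1), float(gate_init)),
                           requires_grad=True)

    def __call__(self, feat: Tensor, embed: Tensor) -> Tensor:
        if embed.shape != feat.shape:
            raise ValueError(f"embed shape {embed.shape} != feature shape {feat.shape}")
        return feat + self.gate * self.proj(embed)


class ResidualEncoder(Module):
    """Strided conv pyramid encoding the transport residual, level-matched.

    Produces one embedding per pyramid level l = 0 .. n_levels-1 with
    channels_at(l) channels at H/2^l resolution, ready for gated fusion
    into the bottleneck and each decoder level.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.n_levels = cfg.n_levels
        self.stem = Conv2d(1, cfg.channels_at(0), 3, rng)
        self.downs = [
            Conv2d(cfg.channels_at(l - 1), cfg.channels_at(l), 3, rng, stride=2,
                   padding=1)
            for l in range(1, cfg.n_levels)
        ]

    def __call__(self, r0: Tensor) -> list[Tensor]:
        embeds = [self.stem(r0)]
        for down in self.downs:
            embeds.append(down(embeds[-1].leaky_relu(0.2)))
        return embeds


class Generator(Module):
    """U-shaped STB encoder-decoder with optional per-level conditioning."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        L = cfg.n_levels
        self.patch_embed = Conv2d(1, cfg.channels_at(0), 3, rng)
        self.encoder = [
            _stack(cfg, lvl, rng) for lvl in range(L)
        ]  # encoder[L-1] is the bottleneck
        self.downs = [Downsample(cfg.channels_at(lvl), rng) for lvl in range(L - 1)]
        self.ups = [Upsample(cfg.channels_at(lvl + 1), rng) for lvl in range(L - 1)]
        self.skips = [
            Conv2d(2 * cfg.channels_at(lvl), cfg.channels_at(lvl), 1, rng)
            for lvl in range(L - 1)
        ]
        self.decoder = [_stack(cfg, lvl, rng) for lvl in range(L - 1)]
        self.fusers = [
            ConditionFuse(cfg.channels_at(lvl), cfg.condition_gate_init, rng)
            for lvl in range(L)
        ]
        # zero-initialized output head: the untrained restoration map is the
        # identity (out = y), so training starts from the degraded baseline
        self.head = Conv2d(cfg.channels_at(0), 1, 3, rng, init="zero")

    def __call__(self, y: Tensor, cond: list[Tensor] | None = None) -> Tensor:
        cfg = self.cfg
        L = cfg.n_levels
        _check_divisible(y.shape, L)
        feat = self.patch_embed(y)
        skips = []
        for lvl in range(L - 1):
            for blk in self.encoder[lvl]:
                feat = blk(feat)
            skips.append(feat)
            feat = self.downs[lvl](feat)
        for blk in self.encoder[L - 1]:
            feat = blk(feat)
        if cond is not None:
            feat = self.fusers[L - 1](feat, cond[L - 1])
        for lvl in range(L - 2, -1, -1):
            feat = self.ups[lvl](feat)
            feat = self.skips[lvl](concat([feat, skips[lvl]], axis=0))
            if cond is not None:
                feat = self.fusers[lvl](feat, cond[lvl])
            for blk in self.decoder[lvl]:
                feat = blk(feat)
        return self.head(feat) + y


def _stack(cfg: ModelConfig, lvl: int, rng: np.random.Generator):
    return [
        SparseTransformerBlock(cfg.channels_at(lvl), cfg.heads_per_level[lvl], cfg, rng)
        for _ in range(cfg.stb_per_level[lvl])
    ]


def _check_divisible(shape, n_levels: int) -> None:
    _, H, W = shape
    f = 2 ** (n_levels - 1)
    if H % f or W % f:
        raise ValueError(f"spatial dims ({H}, {W}) must be divisible by {f}")


class RCST(Module):
    """Two-phase restoration: T(y) = G(y | E(y - G(y))).

    Phase one runs the generator unconditioned; the transport residual
    r0 = y - G(y) is encoded into a feature pyramid and injected into the
    same generator's second pass through gated fusion.  With residual
    conditioning disabled (ablation) the single unconditioned pass is the
    output.
    """

    def __init__(self, cfg: ModelConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.generator = Generator(cfg, rng)
        self.residual_encoder = ResidualEncoder(cfg, rng)

    def generator_stage1(self, y) -> Tensor:
        """Unconditioned preliminary restoration G(y)."""
        return self.generator(_as_image_tensor(y))

    def __call__(self, y) -> tuple[Tensor, Tensor]:
        """Return (restored image, transport residual r0)."""
        yt = _as_image_tensor(y)
        x1 = self.generator(yt)
        r0 = yt - x1
        if not self.cfg.residual_conditioning:
            return x1, r0
        cond = self.residual_encoder(r0)
        out = self.generator(yt, cond=cond)
        return out, r0

    def restore(self, y: np.ndarray) -> np.ndarray:
        """Inference helper: 2-D array in, 2-D array out."""
        out, _ = self(y)
        return out.data[0]


def _as_image_tensor(y) -> Tensor:
    if isinstance(y, Tensor):
        return y if y.ndim == 3 else y.reshape(1, *y.shape)
    y = np.asarray(y, dtype=np.float64)
    if y.ndim == 2:
        y = y[None]
    return Tensor(y)


# -- checkpoint I/O ----------------------------------------------------------


def save_checkpoint(path, model: RCST, epoch: int = 0,
                    rng_state: dict | None = None, extra: dict | None = None) -> None:
    """Single-file NPZ checkpoint: config JSON + parameter blob + counters."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(model.cfg),
        "epoch": int(epoch),
        "extra": extra or {},
        "rng_state": _encode_rng(rng_state),
    }
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[RCST, dict]:
    """Rebuild a model from a checkpoint; raises on version mismatch."""
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta_json"].tobytes()).decode("utf-8"))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"checkpoint version {meta.get('version')} != {CHECKPOINT_VERSION}"
            )
        cfg_d = meta["config"]
        for key in ("stb_per_level", "heads_per_level", "topk_ratios"):
            cfg_d[key] = tuple(cfg_d[key])
        model = RCST(ModelConfig(**cfg_d))
        state = {k[len("param/"):]: npz[k] for k in npz.files if k.startswith("param/")}
    model.load_state(state)
    return model, meta


def _encode_rng(rng_state: dict | None):
    if rng_state is None:
        return None
    # bit_generator state is JSON-serializable except for numpy ints
    return json.loads(json.dumps(rng_state, default=int))
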