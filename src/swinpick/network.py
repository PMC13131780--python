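"""The 3D Swin-Transformer U-Net for voxel-wise multiclass segmentation.

A hierarchical encoder alternates learnable patch merging (block-flatten +
linear projection + normalization, halving each spatial axis) with stacks of
Swin blocks: pre-norm residual units whose attention is restricted to small
3D windows, alternating regular and cyclically shifted windows so information
crosses window boundaries.  Attention logits carry a learnable relative
position bias indexed by the 3D offset between tokens.  The decoder mirrors
the encoder with patch expanding and additive skip fusion, and a final
expansion plus per-voxel linear head produces K class logits at the input
resolution.

Everything here runs on the package's own NumPy autograd tensors; the network
is channel-last internally (B, D, H, W, C) and channel-first at its public
boundary (B, C, D, H, W).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn.autograd import Parameter, Tensor
from .nn.layers import LayerNorm, Linear, Mlp, Module

__all__ = [
    "ModelConfig",
    "SwinUNet3D",
    "PatchMerge3D",
    "PatchExpand3D",
    "WindowAttention3D",
    "SwinBlock3D",
    "window_partition",
    "window_reverse",
    "block_flatten",
    "block_unflatten",
    "relative_position_index",
    "shifted_window_mask",
    "skip_fuse",
]

#: Additive logit penalty for masked attention pairs; softmax weight < 1e-6.
MASK_VALUE = -1.0e4


@dataclasses.dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``depths``/``heads``/``downscale`` are per encoder stage (the decoder
    mirrors them); channel width doubles at each merge starting from
    ``hidden_dim``.  Window attention uses ``window`` tokens per axis with
    cyclic shifts of ``window // 2``.  Every stage depth must be even so
    regular and shifted blocks alternate in pairs, and input spatial extents
    must be divisible by the total downscale factor.
    """

    num_classes: int
    in_channels: int = 4
    hidden_dim: int = 32
    depths: tuple[int, ...] = (2, 6, 6, 2)
    heads: tuple[int, ...] = (3, 6, 12, 24)
    head_dim: int = 32
    window: tuple[int, int, int] = (2, 2, 2)
    downscale: tuple[int, ...] = (2, 2, 2, 2)
    mlp_ratio: int = 4
    dropout: float = 0.1
    skip_style: str = "additive"

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("need at least background + one class")
        if not len(self.depths) == len(self.heads) == len(self.downscale):
            raise ValueError("depths, heads, downscale must have equal length")
        if any(d % 2 for d in self.depths):
            raise ValueError(f"stage depths must be even, got {self.depths}")
        if self.skip_style != "additive":
            raise ValueError(f"unsupported skip_style {self.skip_style!r}")

    @property
    def total_downscale(self) -> int:
        return int(np.prod(self.downscale))

    @classmethod
    def reduced(cls, num_classes: int, **overrides) -> "ModelConfig":
        """Small CPU-friendly preset used for smoke training and tests."""
        kwargs = dict(
            num_classes=num_classes,
            hidden_dim=16,
            depths=(2, 2, 2, 2),
            heads=(1, 2, 4, 8),
            head_dim=16,
            dropout=0.0,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# token/window rearrangement (pure reshapes; exactly invertible)
# ---------------------------------------------------------------------------

def block_flatten(x: Tensor, s: int) -> Tensor:
    """(B, D, H, W, C) -> (B, D/s, H/s, W/s, s^3*C) by flattening s^3 blocks."""
    b, d, h, w, c = x.shape
    if d % s or h % s or w % s:
        raise ValueError(f"spatial dims {(d, h, w)} not divisible by merge factor {s}")
    x = x.reshape(b, d // s, s, h // s, s, w // s, s, c)
    x = x.transpose(0, 1, 3, 5, 2, 4, 6, 7)
    return x.reshape(b, d // s, h // s, w // s, s * s * s * c)


def block_unflatten(x: Tensor, s: int, channels: int) -> Tensor:
    """Inverse of :func:`block_flatten` (also used by patch expansion)."""
    b, d, h, w, _ = x.shape
    x = x.reshape(b, d, h, w, s, s, s, channels)
    x = x.transpose(0, 1, 4, 2, 5, 3, 6, 7)
    return x.reshape(b, d * s, h * s, w * s, channels)


def window_partition(x: Tensor, window: tuple[int, int, int]) -> Tensor:
    """(B, D, H, W, C) -> (B, n_windows, T, C) with T = prod(window)."""
    b, d, h, w, c = x.shape
    wd, wh, ww = window
    if d % wd or h % wh or w % ww:
        raise ValueError(f"spatial dims {(d, h, w)} not divisible by window {window}")
    x = x.reshape(b, d // wd, wd, h // wh, wh, w // ww, ww, c)
    x = x.transpose(0, 1, 3, 5, 2, 4, 6, 7)
    return x.reshape(b, (d // wd) * (h // wh) * (w // ww), wd * wh * ww, c)


def window_reverse(
    xw: Tensor, window: tuple[int, int, int], shape: tuple[int, int, int]
) -> Tensor:
    """Inverse of :func:`window_partition`."""
    d, h, w = shape
    wd, wh, ww = window
    b = xw.shape[0]
    c = xw.shape[-1]
    x = xw.reshape(b, d // wd, h // wh, w // ww, wd, wh, ww, c)
    x = x.transpose(0, 1, 4, 2, 5, 3, 6, 7)
    return x.reshape(b, d, h, w, c)


def relative_position_index(window: tuple[int, int, int]) -> np.ndarray:
    """(T, T) index into the (2d-1)(2h-1)(2w-1) bias table per token pair.

    Entry (i, j) depends only on the 3D offset between tokens i and j inside
    the window, so equal offsets share one learnable bias.
    """
    wd, wh, ww = window
    coords = np.stack(
        np.meshgrid(np.arange(wd), np.arange(wh), np.arange(ww), indexing="ij"), axis=0
    ).reshape(3, -1)
    rel = coords[:, :, None] - coords[:, None, :]  # (3, T, T)
    rel = rel + np.array([wd - 1, wh - 1, ww - 1])[:, None, None]
    return (
        rel[0] * (2 * wh - 1) * (2 * ww - 1) + rel[1] * (2 * ww - 1) + rel[2]
    ).astype(np.int64)


def shifted_window_mask(
    shape: tuple[int, int, int],
    window: tuple[int, int, int],
    shift: tuple[int, int, int],
) -> np.ndarray:
    """Additive (n_windows, T, T) mask for cyclically shifted attention.

    After rolling the grid by ``-shift``, tokens whose original coordinate
    wrapped around a volume boundary sit next to tokens from the far side.
    Pairs originating from different pre-shift regions (wrapped vs not, per
    axis) receive ``MASK_VALUE``; with zero shift the mask is all zeros.
    """
    regions = []
    for extent, sh in zip(shape, shift):
        pos = np.arange(extent)
        # rolled position p holds original coordinate (p + sh) % extent;
        # it wrapped iff p >= extent - sh
        regions.append((pos >= extent - sh).astype(np.int64) if sh else np.zeros(extent, np.int64))
    rid = (
        regions[0][:, None, None] * 4 + regions[1][None, :, None] * 2 + regions[2][None, None, :]
    )
    rid_w = window_partition(Tensor(rid[None, ..., None].astype(np.float32)), window).data
    rid_w = rid_w[0, :, :, 0]  # (n_windows, T)
    same = rid_w[:, :, None] == rid_w[:, None, :]
    return np.where(same, 0.0, MASK_VALUE).astype(np.float32)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class PatchMerge3D(Module):
    """Learnable downsampling: block-flatten, linear projection, layer norm."""

    def __init__(self, in_channels: int, out_channels: int, s: int,
                 rng: np.random.Generator, normalize: bool = True):
        self.s = s
        self.proj = Linear(in_channels * s**3, out_channels, rng)
        self.norm = LayerNorm(out_channels) if normalize else None

    def __call__(self, x: Tensor) -> Tensor:
        y = self.proj(block_flatten(x, self.s))
        return self.norm(y) if self.norm is not None else y


class PatchExpand3D(Module):
    """Learnable upsampling: linear projection, block rearrangement, norm."""

    def __init__(self, in_channels: int, out_channels: int, s: int,
                 rng: np.random.Generator):
        self.s = s
        self.out_channels = out_channels
        self.proj = Linear(in_channels, out_channels * s**3, rng)
        self.norm = LayerNorm(out_channels)

    def __call__(self, x: Tensor) -> Tensor:
        y = block_unflatten(self.proj(x), self.s, self.out_channels)
        return self.norm(y)


class WindowAttention3D(Module):
    """Multi-head self-attention within 3D windows with relative bias."""

    def __init__(self, dim: int, heads: int, head_dim: int,
                 window: tuple[int, int, int], rng: np.random.Generator):
        self.heads = heads
        self.head_dim = head_dim
        self.window = window
        inner = heads * head_dim
        self.qkv = Linear(dim, 3 * inner, rng)
        self.proj = Linear(inner, dim, rng)
        n_offsets = (2 * window[0] - 1) * (2 * window[1] - 1) * (2 * window[2] - 1)
        self.bias_table = Parameter(np.zeros((n_offsets, heads), dtype=np.float32))
        self._index = relative_position_index(window)

    def __call__(self, xw: Tensor, mask: np.ndarray | None = None) -> Tensor:
        b, nw, t, _ = xw.shape
        h, hd = self.heads, self.head_dim
        qkv = self.qkv(xw).reshape(b, nw, t, 3, h, hd).transpose(0, 1, 3, 4, 2, 5)
        q, k, v = qkv[:, :, 0], qkv[:, :, 1], qkv[:, :, 2]  # (b, nw, h, t, hd)
        attn = (q @ k.transpose(0, 1, 2, 4, 3)) * (1.0 / np.sqrt(hd))
        bias = self.bias_table.gather(self._index.reshape(-1))  # (t*t, h)
        bias = bias.reshape(t, t, h).transpose(2, 0, 1)  # (h, t, t)
        attn = attn + bias
        if mask is not None:
            attn = attn + Tensor(mask[None, :, None, :, :])
        attn = attn.softmax(axis=-1)
        out = (attn @ v).transpose(0, 1, 3, 2, 4).reshape(b, nw, t, h * hd)
        return self.proj(out)


class SwinBlock3D(Module):
    """Pre-norm residual unit: window attention then MLP, optionally shifted."""

    def __init__(self, dim: int, heads: int, head_dim: int,
                 window: tuple[int, int, int], shifted: bool,
                 rng: np.random.Generator, mlp_ratio: int = 4, dropout: float = 0.0):
        self.window = window
        self.shift = tuple(w // 2 for w in window) if shifted else (0, 0, 0)
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention3D(dim, heads, head_dim, window, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, rng, ratio=mlp_ratio, dropout=dropout)
        self._mask_cache: dict[tuple[int, int, int], np.ndarray | None] = {}

    def _mask_for(self, shape: tuple[int, int, int]) -> np.ndarray | None:
        if shape not in self._mask_cache:
            if any(self.shift):
                self._mask_cache[shape] = shifted_window_mask(shape, self.window, self.shift)
            else:
                self._mask_cache[shape] = None
        return self._mask_cache[shape]

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None,
                 training: bool = False) -> Tensor:
        spatial = tuple(x.shape[1:4])
        h = self.norm1(x)
        if any(self.shift):
            h = h.roll(tuple(-s for s in self.shift), axis=(1, 2, 3))
        hw = window_partition(h, self.window)
        hw = self.attn(hw, mask=self._mask_for(spatial))
        h = window_reverse(hw, self.window, spatial)
        if any(self.shift):
            h = h.roll(self.shift, axis=(1, 2, 3))
        x = x + h
        return x + self.mlp(self.norm2(x), rng=rng, training=training)


def skip_fuse(f_dec: Tensor, f_enc: Tensor, norm: LayerNorm) -> Tensor:
    """Additive skip fusion: Norm(F_dec + F_enc)."""
    if f_dec.shape != f_enc.shape:
        raise ValueError(f"skip shapes differ: {f_dec.shape} vs {f_enc.shape}")
    return norm(f_dec + f_enc)


class SwinUNet3D(Module):
    """Encoder-decoder with mirrored merge/expand stages and skip fusion.

    Stage layout for the default config on a 64^3 window (hidden h):
    stem h @ 64^3 -> enc 2h @ 32^3 -> 4h @ 16^3 -> 8h @ 8^3 -> bottleneck
    16h @ 4^3, then the mirrored decoder back to h @ 64^3, layer norm, GELU,
    and a per-voxel linear head to K logits (a 1x1x1 convolution).
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        h = config.hidden_dim
        n = len(config.depths)
        self.stem = Linear(config.in_channels, h, rng)
        widths = [h * 2 ** (i + 1) for i in range(n)]
        self.merges = [
            PatchMerge3D(h if i == 0 else widths[i - 1], widths[i], config.downscale[i], rng)
            for i in range(n)
        ]
        self.enc_blocks = [
            [
                SwinBlock3D(widths[i], config.heads[i], config.head_dim, config.window,
                            shifted=(b % 2 == 1), rng=rng, mlp_ratio=config.mlp_ratio,
                            dropout=config.dropout)
                for b in range(config.depths[i])
            ]
            for i in range(n)
        ]
        self.expands = [
            PatchExpand3D(widths[i], widths[i - 1] if i > 0 else h, config.downscale[i], rng)
            for i in range(n - 1, -1, -1)
        ]
        self.fuse_norms = [LayerNorm(widths[i - 1] if i > 0 else h) for i in range(n - 1, -1, -1)]
        self.dec_blocks = [
            [
                SwinBlock3D(widths[i - 1], config.heads[i - 1], config.head_dim, config.window,
                            shifted=(b % 2 == 1), rng=rng, mlp_ratio=config.mlp_ratio,
                            dropout=config.dropout)
                for b in range(config.depths[i - 1])
            ]
            for i in range(n - 1, 0, -1)
        ]
        self.head_norm = LayerNorm(h)
        self.head = Linear(h, config.num_classes, rng)

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None,
                training: bool = False) -> Tensor:
        """(B, C_in, D, H, W) or (C_in, D, H, W) -> logits (B, K, D, H, W)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 4:
            x = x[None]
        if x.ndim != 5 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (B, {self.config.in_channels}, D, H, W) input, got {x.shape}"
            )
        factor = self.config.total_downscale
        if any(s % factor for s in x.shape[2:]):
            raise ValueError(
                f"spatial dims {x.shape[2:]} must be divisible by {factor}"
            )
        t = Tensor(x).transpose(0, 2, 3, 4, 1)  # channel-last
        t = self.stem(t)
        skips = [t]
        for merge, blocks in zip(self.merges, self.enc_blocks):
            t = merge(t)
            for block in blocks:
                t = block(t, rng=rng, training=training)
            skips.append(t)
        # skips[-1] is the bottleneck output itself; decode against the rest
        for level, expand in enumerate(self.expands):
            t = expand(t)
            enc = skips[len(skips) - 2 - level]
            t = skip_fuse(t, enc, self.fuse_norms[level])
            if level < len(self.dec_blocks):
                for block in self.dec_blocks[level]:
                    t = block(t, rng=rng, training=training)
        t = self.head(self.head_norm(t).gelu())
        return t.transpose(0, 4, 1, 2, 3)  # back to channel-first

    # -- weights -------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        named = dict(self.named_parameters())
        missing = sorted(set(named) - set(state))
        extra = sorted(set(state) - set(named))
        if missing or extra:
            raise ValueError(f"state mismatch: missing {missing}, unexpected {extra}")
        for name, p in named.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()
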