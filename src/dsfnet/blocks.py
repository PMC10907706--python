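"""Building blocks of the segmentation network.

CBG      : Conv(3x3) -> BatchNorm -> GELU, the elementary unit.
FCM      : Feature Capture Module — a channel-compressed (C -> C/4) bottleneck
           whose two parallel paths extract local (CBG) and long-range
           (single-layer self-attention over patch tokens) features, fused by
           a 1x1 projection back to C and a global residual.
CBAM     : channel then spatial attention (intra-scale attention).
MFFM     : Multi-scale Feature Fusion Module — per-scale CBAM gated by a
           4-channel inter-scale attention map, concatenation, CBG residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.layers import Parameter, trunc_normal
from .nn.tensor import Tensor, concat

__all__ = ["CBG", "TransformerBlock", "FCM", "FCMConfig", "CBAM", "MFFM"]


class CBG(nn.Module):
    """Conv-BatchNorm-GELU. Padding preserves spatial size; by default the
    channel count is preserved too."""

    def __init__(self, in_ch: int, out_ch: int | None = None):
        super().__init__()
        out_ch = in_ch if out_ch is None else out_ch
        self.in_ch, self.out_ch = in_ch, out_ch
        self.conv = nn.Conv2d(in_ch, out_ch, 3, padding=1)
        self.bn = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_ch:
            raise ValueError(f"CBG expects {self.in_ch} channels, got {x.shape[1]}")
        return self.bn(self.conv(x)).gelu()


@dataclass
class FCMConfig:
    """Hyperparameters of the Feature Capture Module.

    channels    : input channel count C (must be divisible by 4; the module
                  compresses to C/4 internally).
    heads       : attention heads; must divide C/4.
    token_grid  : tokens per side for the attention path (N = token_grid**2
                  patch tokens regardless of resolution, bounding the
                  attention cost identically at every skip level).
    mlp_ratio   : hidden-width multiplier of the token MLP.
    """

    channels: int
    heads: int = 4
    token_grid: int = 14
    mlp_ratio: int = 4

    def __post_init__(self):
        if self.channels % 4:
            raise ValueError(f"FCM channels ({self.channels}) must be divisible by 4")
        if (self.channels // 4) % self.heads:
            raise ValueError(
                f"compressed dim {self.channels // 4} not divisible by "
                f"{self.heads} heads"
            )


class TransformerBlock(nn.Module):
    """One pre-norm encoder layer over non-overlapping patch tokens.

    Tokenizes a (B, D, H, W) map into token_grid**2 patches, linearly embeds
    them to dimension D, adds a learnable positional encoding, applies one
    MSA residual and one MLP residual, and linearly un-projects tokens back
    to the input layout. Output shape equals input shape.
    """

    def __init__(self, dim: int, token_grid: int, heads: int, patch_size: int,
                 mlp_ratio: int = 4):
        super().__init__()
        self.dim, self.token_grid, self.patch_size = dim, token_grid, patch_size
        self.n_tokens = token_grid * token_grid
        d_in = dim * patch_size * patch_size
        self.embed = nn.Linear(d_in, dim)
        self.unembed = nn.Linear(dim, d_in)
        self.pos = Parameter(trunc_normal((1, self.n_tokens, dim)))
        self.ln1 = nn.LayerNorm(dim)
        self.msa = nn.MultiheadSelfAttention(dim, heads)
        self.ln2 = nn.LayerNorm(dim)
        hidden = dim * mlp_ratio
        self.fc1 = nn.Linear(dim, hidden)
        self.fc2 = nn.Linear(hidden, dim)

    def forward(self, x: Tensor) -> Tensor:
        B, D, H, W = x.shape
        g, p = self.token_grid, self.patch_size
        if H != g * p or W != g * p:
            raise ValueError(
                f"spatial size ({H},{W}) incompatible with token_grid={g} and "
                f"patch_size={p} (expected {g * p})"
            )
        # (B,D,H,W) -> (B, N, D*p*p) patch tokens
        tok = x.reshape(B, D, g, p, g, p).transpose(0, 2, 4, 1, 3, 5).reshape(
            B, self.n_tokens, D * p * p
        )
        z0 = self.embed(tok) + self.pos
        z1 = z0 + self.msa(self.ln1(z0))
        z2 = z1 + self.fc2(self.fc1(self.ln2(z1)).gelu())
        out = self.unembed(z2)
        return out.reshape(B, g, g, D, p, p).transpose(0, 3, 1, 4, 2, 5).reshape(
            B, D, H, W
        )


class FCM(nn.Module):
    """Feature Capture Module.

    F' = conv1x1(F) with C/4 channels; output = F + conv1x1(CBG(F') + T(F'))
    where T is the single-layer self-attention path. The expanding 1x1
    convolution is zero-initialized so a freshly built FCM is the identity.
    """

    def __init__(self, cfg: FCMConfig, spatial_size: int):
        super().__init__()
        if spatial_size % cfg.token_grid:
            raise ValueError(
                f"spatial size {spatial_size} not divisible by "
                f"token_grid {cfg.token_grid}"
            )
        self.cfg = cfg
        c, c4 = cfg.channels, cfg.channels // 4
        self.compress = nn.Conv2d(c, c4, 1)
        self.cbg = CBG(c4)
        self.attn = TransformerBlock(
            c4, cfg.token_grid, cfg.heads,
            patch_size=spatial_size // cfg.token_grid, mlp_ratio=cfg.mlp_ratio,
        )
        self.expand = nn.Conv2d(c4, c, 1, zero_init=True)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.channels:
            raise ValueError(
                f"FCM expects {self.cfg.channels} channels, got {x.shape[1]}"
            )
        f = self.compress(x)
        return x + self.expand(self.cbg(f) + self.attn(f))


class CBAM(nn.Module):
    """Convolutional Block Attention Module (channel then spatial attention)."""

    def __init__(self, channels: int, reduction: int | None = None):
        super().__init__()
        if reduction is None:
            reduction = 16 if channels >= 64 else 4
        if channels < reduction:
            raise ValueError(f"channels ({channels}) < reduction ratio ({reduction})")
        self.channels = channels
        hidden = max(channels // reduction, 1)
        self.fc1 = nn.Linear(channels, hidden, bias=False)
        self.fc2 = nn.Linear(hidden, channels, bias=False)
        self.spatial_conv = nn.Conv2d(2, 1, 7, padding=3)

    def channel_attention(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        avg = x.mean(axis=(2, 3))  # (B, C)
        mx_data = x.data.max(axis=(2, 3))
        # max-pool gradient: route through the argmax positions
        flat = x.reshape(B, C, H * W)
        idx = x.data.reshape(B, C, H * W).argmax(axis=-1)
        onehot = np.zeros((B, C, H * W), dtype=np.float32)
        np.put_along_axis(onehot, idx[..., None], 1.0, axis=-1)
        mx = (flat * Tensor(onehot)).sum(axis=-1)
        assert np.allclose(mx.data, mx_data, atol=1e-6)
        shared = lambda v: self.fc2(self.fc1(v).relu())
        return (shared(avg) + shared(mx)).sigmoid()  # (B, C)

    def spatial_attention(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        avg = x.mean(axis=1, keepdims=True)
        flat = x.transpose(0, 2, 3, 1)  # (B,H,W,C)
        idx = flat.data.argmax(axis=-1)
        onehot = np.zeros(flat.shape, dtype=np.float32)
        np.put_along_axis(onehot, idx[..., None], 1.0, axis=-1)
        mx = (flat * Tensor(onehot)).sum(axis=-1).reshape(B, 1, H, W)
        return self.spatial_conv(concat([avg, mx], axis=1)).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        mc = self.channel_attention(x).reshape(B, C, 1, 1)
        xc = x * mc
        return xc * self.spatial_attention(xc)


class MFFM(nn.Module):
    """Multi-scale Feature Fusion Module over four same-shape feature maps.

    Pathway 1 applies CBAM per scale (intra-scale attention). Pathway 2
    computes a 4-channel inter-scale attention map A from the concatenated
    raw inputs via a 7x7 convolution (sigmoid-bounded). Gated per-scale maps
    are concatenated to 4*C channels and fused by a residual CBG.
    """

    def __init__(self, channels: int, reduction: int | None = None):
        super().__init__()
        self.channels = channels
        self.cbam = [CBAM(channels, reduction) for _ in range(4)]
        self.interscale_conv = nn.Conv2d(4 * channels, 4, 7, padding=3)
        self.fuse = CBG(4 * channels)

    def forward(self, f1: Tensor, f2: Tensor, f3: Tensor, f4: Tensor) -> Tensor:
        feats = [f1, f2, f3, f4]
        shape = feats[0].shape
        for f in feats[1:]:
            if f.shape != shape:
                raise ValueError(
                    f"MFFM inputs must share shape; got {f.shape} vs {shape}"
                )
        A = self.interscale_conv(concat(feats, axis=1)).sigmoid()  # (B,4,H,W)
        gated = [
            self.cbam[i](feats[i]) * A[:, i : i + 1] for i in range(4)
        ]
        fc = concat(gated, axis=1)
        return self.fuse(fc) + fc
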