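"""DSFNet: a U-shaped encoder-decoder with Feature Capture Modules in its
skip connections and a Multi-scale Feature Fusion Module before the head.

Layout (depth 3):

    encoder   C0 @ S   -> 2C0 @ S/2 -> 4C0 @ S/4     (two CBG blocks per stage)
    bottleneck 8C0 @ S/8
    decoder   4C0 @ S/4 -> 2C0 @ S/2 -> C0 @ S       (x2 transposed conv + skip)

Each skip passes through an FCM (identity pass-through when disabled). The
bottleneck output and the three decoder outputs are 1x1-projected to C0,
bilinearly resized to full resolution and fused by the MFFM; the head is a
1x1 convolution to one channel followed by a sigmoid. Ablation flags
``use_fcm`` / ``use_mffm`` reconstruct the reduced variants.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

from . import nn
from .blocks import CBG, FCM, FCMConfig, MFFM
from .nn import functional as F
from .nn.tensor import Tensor, concat

__all__ = ["NetworkConfig", "DSFNet", "build_dsfnet"]

DEPTH = 3  # three down/up stages


@dataclass
class NetworkConfig:
    in_channels: int = 1
    base_channels: int = 32
    use_fcm: bool = True
    use_mffm: bool = True
    input_size: int = 224
    token_grid: int = 14
    heads: int = 4
    mlp_ratio: int = 4
    cbam_reduction: int | None = None

    def __post_init__(self):
        if self.base_channels % 4:
            raise ValueError(
                f"base_channels ({self.base_channels}) must be divisible by 4"
            )
        if self.input_size % (2 ** DEPTH):
            raise ValueError(
                f"input_size ({self.input_size}) must be divisible by {2 ** DEPTH}"
            )
        if self.use_fcm:
            for level in range(DEPTH):
                res = self.input_size // (2 ** level)
                if res % self.token_grid:
                    raise ValueError(
                        f"skip resolution {res} (level {level}) not divisible "
                        f"by token_grid {self.token_grid}"
                    )
                c4 = self.base_channels * (2 ** level) // 4
                if c4 % self.heads:
                    raise ValueError(
                        f"compressed channels {c4} (level {level}) not "
                        f"divisible by heads {self.heads}"
                    )

    def to_dict(self) -> dict:
        return asdict(self)


class _Stage(nn.Module):
    """Two stacked CBG blocks."""

    def __init__(self, in_ch: int, out_ch: int):
        super().__init__()
        self.b1 = CBG(in_ch, out_ch)
        self.b2 = CBG(out_ch)

    def forward(self, x):
        return self.b2(self.b1(x))


class DSFNet(nn.Module):
    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        self.cfg = cfg
        c0 = cfg.base_channels
        self.encoder_channels = (c0, 2 * c0, 4 * c0)
        self.bottleneck_channels = 8 * c0

        self.enc = [
            _Stage(cfg.in_channels, c0),
            _Stage(c0, 2 * c0),
            _Stage(2 * c0, 4 * c0),
        ]
        self.pool = nn.MaxPool2d()
        self.bottleneck = _Stage(4 * c0, 8 * c0)

        if cfg.use_fcm:
            self.fcm = [
                FCM(
                    FCMConfig(
                        channels=self.encoder_channels[level],
                        heads=cfg.heads,
                        token_grid=cfg.token_grid,
                        mlp_ratio=cfg.mlp_ratio,
                    ),
                    spatial_size=cfg.input_size // (2 ** level),
                )
                for level in range(DEPTH)
            ]
        else:
            self.fcm = []

        # decoder, deepest first
        self.up = [
            nn.ConvTranspose2d(8 * c0, 4 * c0),
            nn.ConvTranspose2d(4 * c0, 2 * c0),
            nn.ConvTranspose2d(2 * c0, c0),
        ]
        self.dec = [
            _Stage(8 * c0, 4 * c0),
            _Stage(4 * c0, 2 * c0),
            _Stage(2 * c0, c0),
        ]

        if cfg.use_mffm:
            scale_chs = (8 * c0, 4 * c0, 2 * c0, c0)
            self.proj = [nn.Conv2d(ch, c0, 1) for ch in scale_chs]
            self.mffm = MFFM(c0, cfg.cbam_reduction)
            self.head = nn.Conv2d(4 * c0, 1, 1)
        else:
            self.proj = []
            self.mffm = None
            self.head = nn.Conv2d(c0, 1, 1)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        if not isinstance(x, Tensor):
            x = Tensor(x)
        B, C, H, W = x.shape
        if C != cfg.in_channels or H != cfg.input_size or W != cfg.input_size:
            raise ValueError(
                f"expected input (B,{cfg.in_channels},{cfg.input_size},"
                f"{cfg.input_size}), got {x.shape}"
            )
        skips = []
        for enc in self.enc:
            x = enc(x)
            skips.append(x)
            x = self.pool(x)
        x = self.bottleneck(x)
        if cfg.use_fcm:
            skips = [self.fcm[i](s) for i, s in enumerate(skips)]

        scales = [x]  # bottleneck output
        for i in range(DEPTH):
            x = self.up[i](x)
            x = self.dec[i](concat([x, skips[DEPTH - 1 - i]], axis=1))
            scales.append(x)

        if cfg.use_mffm:
            full = (cfg.input_size, cfg.input_size)
            fused = self.mffm(
                *[
                    F.bilinear_resize(self.proj[i](scales[i]), full)
                    for i in range(4)
                ]
            )
            logits = self.head(fused)
        else:
            logits = self.head(x)
        return logits.sigmoid()


def build_dsfnet(cfg: NetworkConfig) -> DSFNet:
    """Construct a DSFNet from its configuration."""
    return DSFNet(cfg)
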