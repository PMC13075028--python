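"""Boundary-aware hierarchical segmentation network.

The network is a SegFormer-style design: a four-stage hierarchical
transformer encoder (overlapping patch embedding, efficient self-attention
with spatial reduction, Mix-FFN) producing a feature pyramid C1..C4 at
strides 4/8/16/32, an all-MLP decoder, plus two task-specific additions for
low-contrast floating-algae scenes:

* **Efficient channel attention (ECA)** recalibrates the channels of the
  shallow stages (C1, C2 by default). A global average pool yields a channel
  descriptor, a bias-free 1-D convolution with adaptive odd kernel size models
  local cross-channel interaction, and a sigmoid gate rescales each channel.
* **A parallel boundary branch** consumes the same recalibrated shallow
  features the decoder sees: C2' is bilinearly upsampled to the C1' grid,
  the two are concatenated (64+128=192 channels in the base configuration),
  passed through a 3x3 conv + BN + ReLU into 64 channels, classified per
  pixel by a 1x1 conv, and upsampled to input resolution as a single-channel
  boundary logits map.

Functional forms of the ECA operations (:func:`channel_descriptor`,
:func:`channel_weights`, :func:`recalibrate`) are exposed on plain NumPy
arrays in the H x W x C convention so they can be checked independently of
the trained layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit

from . import nn
from .errors import ConfigError, InputError, ShapeError
from .nn import functional as F
from .nn.tensor import Tensor, concat

__all__ = [
    "adaptive_kernel_size", "channel_descriptor", "channel_weights",
    "recalibrate", "fuse_shallow", "EcaConfig", "ModelConfig",
    "PredictionPair", "SegmentationModel", "normalize_composite", "VARIANTS",
]

STRIDES = (4, 8, 16, 32)


# --------------------------------------------------------------------- ECA ops
def adaptive_kernel_size(channels: int, gamma: int = 2, b: int = 1) -> int:
    """Adaptive ECA kernel size: nearest odd integer to log2(C)/gamma + b.

    Exact ties round upward; the result is floored at 3 so a degenerate
    single-tap kernel never occurs. 64 and 128 channels both map to 5 with
    the default gamma=2, b=1.
    """
    if channels < 1 or gamma < 1:
        raise ConfigError(f"need channels >= 1 and gamma >= 1, got {channels}, {gamma}")
    t = math.log2(channels) / gamma + b
    n = math.floor((t - 1.0) / 2.0 + 0.5)  # nearest odd 2n+1, half rounds up
    return max(2 * int(n) + 1, 3)


def channel_descriptor(feat: np.ndarray) -> np.ndarray:
    """Global-average-pool an H x W x C feature map to a length-C vector."""
    feat = np.asarray(feat, dtype=float)
    if feat.ndim != 3 or feat.size == 0:
        raise InputError("feature map must be non-empty H x W x C")
    return feat.mean(axis=(0, 1))


def channel_weights(z: np.ndarray, k: int, conv_weights: np.ndarray,
                    bias: float = 0.0) -> np.ndarray:
    """Sigmoid-gated 1-D convolution of a channel descriptor.

    The kernel slides over the channel axis with zero padding (k-1)/2 so the
    output length equals the number of channels; outputs lie in (0, 1).
    """
    if k % 2 == 0:
        raise ConfigError("ECA kernel size must be odd")
    w = np.asarray(conv_weights, dtype=float)
    if w.shape != (k,):
        raise ShapeError(f"conv_weights must have length {k}")
    z = np.asarray(z, dtype=float)
    pad = (k - 1) // 2
    zp = np.pad(z, pad)
    c = z.shape[0]
    conv = np.array([w @ zp[i:i + k] for i in range(c)])
    return expit(conv + bias)


def recalibrate(feat: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Channel-wise rescaling F_hat[i,j,c] = F[i,j,c] * s[c]."""
    feat = np.asarray(feat, dtype=float)
    s = np.asarray(s, dtype=float)
    if feat.ndim != 3 or s.shape != (feat.shape[2],):
        raise ShapeError(f"weights of length {s.shape} do not match {feat.shape}")
    return feat * s[None, None, :]


# ------------------------------------------------------------------- configs
@dataclass(frozen=True)
class EcaConfig:
    gamma: int = 2
    b: int = 1
    active_stages: tuple[int, ...] = (1, 2)
    conv_bias: bool = False

    def __post_init__(self):
        if self.gamma < 1:
            raise ConfigError("gamma must be >= 1")
        if not self.active_stages:
            raise ConfigError("active_stages must be non-empty when ECA is enabled")
        if any(s not in (1, 2, 3, 4) for s in self.active_stages):
            raise ConfigError(f"unknown stage in {self.active_stages}")


VARIANTS: dict[str, dict] = {
    "b2": dict(stage_channels=(64, 128, 320, 512), depths=(3, 4, 6, 3),
               num_heads=(1, 2, 5, 8), sr_ratios=(8, 4, 2, 1),
               decoder_dim=768, mlp_ratio=4),
    "tiny": dict(stage_channels=(32, 64, 128, 256), depths=(2, 2, 2, 2),
                 num_heads=(1, 2, 4, 8), sr_ratios=(8, 4, 2, 1),
                 decoder_dim=256, mlp_ratio=4),
    "micro": dict(stage_channels=(16, 32, 64, 128), depths=(1, 1, 1, 1),
                  num_heads=(1, 2, 2, 4), sr_ratios=(4, 2, 1, 1),
                  decoder_dim=64, mlp_ratio=2),
}


@dataclass(frozen=True)
class ModelConfig:
    stage_channels: tuple[int, ...] = (64, 128, 320, 512)
    depths: tuple[int, ...] = (3, 4, 6, 3)
    num_heads: tuple[int, ...] = (1, 2, 5, 8)
    sr_ratios: tuple[int, ...] = (8, 4, 2, 1)
    decoder_dim: int = 768
    mlp_ratio: int = 4
    num_classes: int = 2
    in_channels: int = 3
    eca: EcaConfig | None = field(default_factory=EcaConfig)
    boundary_branch: bool = True
    boundary_hidden: int = 64

    def __post_init__(self):
        for name in ("stage_channels", "depths", "num_heads", "sr_ratios"):
            if len(getattr(self, name)) != 4:
                raise ConfigError(f"{name} must have 4 entries")
        if any(a >= b for a, b in zip(self.stage_channels, self.stage_channels[1:])):
            raise ConfigError("stage channel counts must strictly increase")

    @classmethod
    def from_variant(cls, name: str, **overrides) -> "ModelConfig":
        if name not in VARIANTS:
            raise ConfigError(f"unknown variant {name!r}; choose from {sorted(VARIANTS)}")
        kw = dict(VARIANTS[name])
        kw.update(overrides)
        return cls(**kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["eca"] = None if self.eca is None else asdict(self.eca)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if d.get("eca") is not None:
            e = dict(d["eca"])
            e["active_stages"] = tuple(e["active_stages"])
            d["eca"] = EcaConfig(**e)
        for name in ("stage_channels", "depths", "num_heads", "sr_ratios"):
            d[name] = tuple(d[name])
        return cls(**d)


@dataclass
class PredictionPair:
    """Full-resolution segmentation logits and boundary logits.

    ``seg_logits``: (N, 2, H, W); ``boundary_logits``: (N, 1, H, W) or None
    when the boundary branch is disabled.
    """
    seg_logits: Tensor
    boundary_logits: Tensor | None

    def seg_mask(self) -> np.ndarray:
        """Argmax class map, (N, H, W) in {0,1}."""
        return np.argmax(self.seg_logits.data, axis=1).astype(np.uint8)


# ------------------------------------------------------------------- helpers
def normalize_composite(image: np.ndarray) -> np.ndarray:
    """8-bit H x W x 3 composite -> float (3, H, W) in [-1, 1]."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise InputError(f"composite must be H x W x 3, got {image.shape}")
    scaled = ((image.astype(np.float32) / 255.0) - 0.5) / 0.5
    return scaled.transpose(2, 0, 1)


def _to_tokens(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    return x.transpose(0, 2, 3, 1).reshape(n, h * w, c)


def _to_map(x: Tensor, h: int, w: int) -> Tensor:
    n, l, c = x.shape
    return x.reshape(n, h, w, c).transpose(0, 3, 1, 2)


def fuse_shallow(c1p: Tensor, c2p: Tensor) -> Tensor:
    """Upsample C2' x2 onto the C1' grid and concatenate channels."""
    if c1p.shape[2] != 2 * c2p.shape[2] or c1p.shape[3] != 2 * c2p.shape[3]:
        raise ShapeError(
            f"C2' sides must be exactly half of C1': got {c2p.shape} vs {c1p.shape}")
    up = F.bilinear_resize(c2p, c1p.shape[2], c1p.shape[3])
    return concat([c1p, up], axis=1)


# ------------------------------------------------------------------- modules
class EcaLayer(nn.Module):
    """ECA recalibration: GAP -> bias-free 1-D conv (adaptive k) -> sigmoid."""

    def __init__(self, channels: int, cfg: EcaConfig, rng: np.random.Generator):
        super().__init__()
        self.kernel_size = adaptive_kernel_size(channels, cfg.gamma, cfg.b)
        self.conv = nn.Conv1dChannel(self.kernel_size, rng, bias=cfg.conv_bias)
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        z = x.mean(axis=(2, 3))               # (N, C) channel descriptors
        s = self.conv(z).sigmoid()
        return x * s.reshape(n, c, 1, 1)


class EfficientSelfAttention(nn.Module):
    def __init__(self, dim: int, heads: int, sr_ratio: int, rng: np.random.Generator):
        super().__init__()
        if dim % heads:
            raise ConfigError("dim must be divisible by heads")
        self.heads = heads
        self.dim = dim
        self.scale = (dim // heads) ** -0.5
        self.q = nn.Linear(dim, dim, rng)
        self.kv = nn.Linear(dim, 2 * dim, rng)
        self.proj = nn.Linear(dim, dim, rng)
        self.sr_ratio = sr_ratio
        if sr_ratio > 1:
            self.sr = nn.Conv2d(dim, dim, sr_ratio, rng, stride=sr_ratio)
            self.sr_norm = nn.LayerNorm(dim)

    def forward(self, x: Tensor, h: int, w: int) -> Tensor:
        n, l, c = x.shape
        hd = c // self.heads
        q = self.q(x).reshape(n, l, self.heads, hd).transpose(0, 2, 1, 3)
        if self.sr_ratio > 1:
            red = self.sr(_to_map(x, h, w))
            x_kv = self.sr_norm(_to_tokens(red))
        else:
            x_kv = x
        l2 = x_kv.shape[1]
        kv = self.kv(x_kv).reshape(n, l2, 2, self.heads, hd)
        k = kv[:, :, 0].transpose(0, 2, 1, 3)
        v = kv[:, :, 1].transpose(0, 2, 1, 3)
        attn = ((q @ k.transpose(0, 1, 3, 2)) * self.scale).softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(n, l, c)
        return self.proj(out)


class MixFFN(nn.Module):
    """Feed-forward with a 3x3 depthwise convolution providing positional mixing."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.dw = nn.DepthwiseConv2d(hidden, 3, rng, padding=1)
        self.fc2 = nn.Linear(hidden, dim, rng)

    def forward(self, x: Tensor, h: int, w: int) -> Tensor:
        t = self.fc1(x)
        t = _to_tokens(self.dw(_to_map(t, h, w)))
        return self.fc2(t.gelu())


class TransformerBlock(nn.Module):
    def __init__(self, dim: int, heads: int, sr_ratio: int, mlp_ratio: int,
                 rng: np.random.Generator):
        super().__init__()
        self.norm1 = nn.LayerNorm(dim)
        self.attn = EfficientSelfAttention(dim, heads, sr_ratio, rng)
        self.norm2 = nn.LayerNorm(dim)
        self.ffn = MixFFN(dim, dim * mlp_ratio, rng)

    def forward(self, x: Tensor, h: int, w: int) -> Tensor:
        x = x + self.attn(self.norm1(x), h, w)
        x = x + self.ffn(self.norm2(x), h, w)
        return x


class EncoderStage(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, patch_kernel: int, stride: int,
                 depth: int, heads: int, sr_ratio: int, mlp_ratio: int,
                 rng: np.random.Generator):
        super().__init__()
        self.embed = nn.Conv2d(in_ch, out_ch, patch_kernel, rng,
                               stride=stride, padding=patch_kernel // 2)
        self.embed_norm = nn.LayerNorm(out_ch)
        self.blocks = nn.Sequential(*[
            TransformerBlock(out_ch, heads, sr_ratio, mlp_ratio, rng)
            for _ in range(depth)
        ])
        self.out_norm = nn.LayerNorm(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        emb = self.embed(x)
        h, w = emb.shape[2], emb.shape[3]
        t = self.embed_norm(_to_tokens(emb))
        for blk in self.blocks._order:
            t = blk(t, h, w)
        return _to_map(self.out_norm(t), h, w)


class Encoder(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        chans = cfg.stage_channels
        ins = (cfg.in_channels,) + chans[:3]
        kernels = (7, 3, 3, 3)
        strides = (4, 2, 2, 2)
        for i in range(4):
            setattr(self, f"stage{i + 1}", EncoderStage(
                ins[i], chans[i], kernels[i], strides[i], cfg.depths[i],
                cfg.num_heads[i], cfg.sr_ratios[i], cfg.mlp_ratio, rng))

    def stages(self) -> list[EncoderStage]:
        return [self.stage1, self.stage2, self.stage3, self.stage4]


class MLPDecoder(nn.Module):
    """Per-stage linear projection, upsample to the stride-4 grid, fuse, classify."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        for i, c in enumerate(cfg.stage_channels):
            setattr(self, f"proj{i + 1}", nn.Linear(c, cfg.decoder_dim, rng))
        self.fuse = nn.Conv2d(4 * cfg.decoder_dim, cfg.decoder_dim, 1, rng)
        self.fuse_bn = nn.BatchNorm2d(cfg.decoder_dim)
        self.classifier = nn.Conv2d(cfg.decoder_dim, cfg.num_classes, 1, rng)

    def forward(self, pyramid: list[Tensor], out_side: int) -> Tensor:
        if len(pyramid) != 4:
            raise ShapeError(f"expected a 4-stage pyramid, got {len(pyramid)}")
        th, tw = pyramid[0].shape[2], pyramid[0].shape[3]
        ups = []
        for i, feat in enumerate(pyramid):
            h, w = feat.shape[2], feat.shape[3]
            proj = getattr(self, f"proj{i + 1}")(_to_tokens(feat))
            ups.append(F.bilinear_resize(_to_map(proj, h, w), th, tw))
        fused = self.fuse(concat(ups[::-1], axis=1))
        fused = self.fuse_bn(fused).relu()
        logits = self.classifier(fused)
        return F.bilinear_resize(logits, out_side, out_side)


class BoundaryBranch(nn.Module):
    """3x3 conv (no bias) + BN + ReLU -> 1x1 conv -> bilinear upsample."""

    def __init__(self, in_ch: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.conv3 = nn.Conv2d(in_ch, hidden, 3, rng, padding=1, bias=False)
        self.bn = nn.BatchNorm2d(hidden)
        self.conv1 = nn.Conv2d(hidden, 1, 1, rng, bias=True)
        self.in_ch = in_ch

    def forward(self, fused: Tensor, out_side: int) -> Tensor:
        if out_side < fused.shape[2]:
            raise ConfigError("output side smaller than the fused feature side")
        x = self.bn(self.conv3(fused)).relu()
        return F.bilinear_resize(self.conv1(x), out_side, out_side)


class SegmentationModel(nn.Module):
    """Full network: encoder + ECA recalibration + MLP decoder + boundary branch."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        super().__init__()
        cfg = config if config is not None else ModelConfig()
        rng = np.random.default_rng(seed)
        self.config = cfg
        self.encoder = Encoder(cfg, rng)
        if cfg.eca is not None:
            for s in cfg.eca.active_stages:
                setattr(self, f"eca{s}",
                        EcaLayer(cfg.stage_channels[s - 1], cfg.eca, rng))
        self.decoder = MLPDecoder(cfg, rng)
        if cfg.boundary_branch:
            in_ch = cfg.stage_channels[0] + cfg.stage_channels[1]
            self.boundary = BoundaryBranch(in_ch, cfg.boundary_hidden, rng)

    # -------------------------------------------------------------- components
    def components(self) -> dict[str, nn.Module]:
        out = {"encoder": self.encoder, "decoder": self.decoder}
        eca = {k: m for k, m in self._modules.items() if k.startswith("eca")}
        if eca:
            holder = nn.Module()
            for k, m in eca.items():
                setattr(holder, k, m)
            out["eca"] = holder
        if self.config.boundary_branch:
            out["boundary_branch"] = self.boundary
        return out

    def eca_layer(self, stage: int) -> EcaLayer | None:
        return getattr(self, f"eca{stage}", None)

    # ------------------------------------------------------------------ passes
    def _check_input(self, x: Tensor) -> int:
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise InputError(
                f"expected (N, {self.config.in_channels}, H, W), got {x.shape}")
        side = x.shape[2]
        if x.shape[3] != side:
            raise InputError("inputs must be square tiles")
        if side % 32:
            raise InputError(f"input side {side} not divisible by 32")
        return side

    def encode(self, x: Tensor) -> list[Tensor]:
        """Feature pyramid C1..C4; active stages are ECA-recalibrated in place."""
        self._check_input(x)
        feats = []
        cur = x
        for i, stage in enumerate(self.encoder.stages(), start=1):
            cur = stage(cur)
            eca = self.eca_layer(i)
            if eca is not None:
                cur = eca(cur)
            feats.append(cur)
        return feats

    def decode(self, pyramid: list[Tensor], out_side: int) -> Tensor:
        return self.decoder(pyramid, out_side)

    def forward(self, x: Tensor) -> PredictionPair:
        side = self._check_input(x)
        pyramid = self.encode(x)
        seg = self.decode(pyramid, side)
        bnd = None
        if self.config.boundary_branch:
            bnd = self.boundary(fuse_shallow(pyramid[0], pyramid[1]), side)
        return PredictionPair(seg, bnd)

    def predict(self, image: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        """Segment one 8-bit H x W x 3 composite.

        Returns (seg_logits H x W x 2, boundary_logits H x W x 1 or None).
        """
        x = Tensor(normalize_composite(image)[None])
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                pair = self.forward(x)
        finally:
            self.train(was_training)
        seg = pair.seg_logits.data[0].transpose(1, 2, 0)
        bnd = None
        if pair.boundary_logits is not None:
            bnd = pair.boundary_logits.data[0].transpose(1, 2, 0)
        return seg, bnd
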