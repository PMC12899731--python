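"""Detector architecture: a nano-scale one-stage anchor-free network.

The layout follows the modern CSP-style nano detector family: a strided
convolutional backbone with C3k2 stages, SPPF pooling and a
position-sensitive attention stage (C2PSA); a PAN-style neck with two
top-down and two bottom-up fusions; and a decoupled anchor-free head with
distribution-focal box regression over three strides (8, 16, 32).

Two structural switches define the model variants:

* ``repghost`` — replaces the backbone's convolutions with re-parameterizable
  ghost blocks (:mod:`shrimpdet.repghost`), shrinking parameters and MACs.
* ``ensimam`` — inserts the parameter-free attention
  (:mod:`shrimpdet.ensimam`) after each neck fusion block.

Channel widths derive from the base plan (64, 128, 256, 512, 1024) scaled
by ``width_mult`` and capped at ``max_channels``; block repeats scale with
``depth_mult`` (nano: 0.25 / 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.layers import Conv2d, ConvBNAct, Identity, MaxPool2d
from .ensimam import EnSimAM, EnSimAMConfig
from .repghost import GhostConfig, RepGhostBlock

__all__ = ["ModelConfig", "DetectionModel", "baseline_config", "shrimp_config",
           "tiny_config", "make_anchors"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    input_size: int = 640
    num_classes: int = 1            # the single "residual feed" class by default
    width_mult: float = 0.25
    depth_mult: float = 0.50
    max_channels: int = 1024
    reg_max: int = 16               # distribution-focal bins per box side
    repghost: bool = False
    ghost_scope: str = "deep"       # deep | bottlenecks | backbone | backbone_psa
    ghost_ratio: int = 2
    ensimam: bool = False
    ensimam_cfg: EnSimAMConfig = field(default_factory=EnSimAMConfig)
    use_psa: bool = True
    loss_weights: tuple = (1.0, 0.5, 7.5)   # (obj, cls, loc)
    nms_conf: float = 0.25
    nms_iou: float = 0.45
    init_seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.input_size % 32 != 0:
            raise ValueError("input_size must be a multiple of 32")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if any(w < 0 for w in self.loss_weights):
            raise ValueError("loss weights must be non-negative")
        if self.ghost_scope not in ("deep", "bottlenecks", "backbone", "backbone_psa"):
            raise ValueError("unknown ghost_scope")

    def channels(self):
        base = (64, 128, 256, 512, 1024)
        return tuple(max(8, int(round(min(c, self.max_channels) * self.width_mult)))
                     for c in base)

    def repeats(self, n: int = 2) -> int:
        return max(1, int(round(n * self.depth_mult)))


def baseline_config(**kw) -> ModelConfig:
    """Unmodified nano detector (the ablation reference)."""
    kw.setdefault("repghost", False)
    kw.setdefault("ensimam", False)
    return ModelConfig(**kw)


def shrimp_config(**kw) -> ModelConfig:
    """Lightweight variant: ghost backbone + parameter-free neck attention."""
    kw.setdefault("repghost", True)
    kw.setdefault("ensimam", True)
    return ModelConfig(**kw)


def tiny_config(baseline: bool = False, **kw) -> ModelConfig:
    """Desk-scale model for CPU training experiments (width 1/8, reg_max 8)."""
    defaults = dict(input_size=160, width_mult=0.125, depth_mult=0.34,
                    reg_max=8, use_psa=False,
                    repghost=not baseline, ensimam=not baseline)
    defaults.update(kw)
    return ModelConfig(**defaults)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class _Builder:
    """Carries rng/dtype/ghost policy through construction."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.init_seed)
        self.dtype = np.dtype(cfg.dtype).type

    def conv(self, c1, c2, k=1, s=1, ghost=False, act=True, groups=1):
        if ghost and self.cfg.repghost and groups == 1 and c2 % self.cfg.ghost_ratio == 0 \
                and c2 // self.cfg.ghost_ratio >= 4:
            gcfg = GhostConfig(c1, c2, self.cfg.ghost_ratio, primary_kernel=k,
                               cheap_kernel=3, stride=s)
            return RepGhostBlock(gcfg, rng=self.rng, dtype=self.dtype, act=act)
        return ConvBNAct(c1, c2, k, s, groups=groups, act=act,
                         rng=self.rng, dtype=self.dtype)


class Bottleneck(nn.Module):
    def __init__(self, b: _Builder, c1, c2, shortcut=True, k=(3, 3), e=0.5, ghost=False):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = b.conv(c1, c_, k[0], ghost=ghost)
        self.cv2 = b.conv(c_, c2, k[1], ghost=ghost)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return ag.add(x, y) if self.add else y


class C3k(nn.Module):
    """CSP stage with n serial 3x3 bottlenecks at full inner width."""

    def __init__(self, b: _Builder, c1, c2, n=2, shortcut=True, e=0.5,
                 ghost_inner=False, ghost_trans=False):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = b.conv(c1, c_, 1, ghost=ghost_trans)
        self.cv2 = b.conv(c1, c_, 1, ghost=ghost_trans)
        self.cv3 = b.conv(2 * c_, c2, 1, ghost=ghost_trans)
        self.m = nn.Sequential(*[Bottleneck(b, c_, c_, shortcut, k=(3, 3), e=1.0,
                                            ghost=ghost_inner) for _ in range(n)])

    def forward(self, x):
        return self.cv3(ag.concat([self.m(self.cv1(x)), self.cv2(x)], axis=1))


class C3k2(nn.Module):
    """Split-transform-merge stage; inner units are bottlenecks or C3k blocks."""

    def __init__(self, b: _Builder, c1, c2, n=1, c3k=False, e=0.5, shortcut=True,
                 ghost_inner=False, ghost_trans=False):
        super().__init__()
        self.c = int(c2 * e)
        self.cv1 = b.conv(c1, 2 * self.c, 1, ghost=ghost_trans)
        self.cv2 = b.conv((2 + n) * self.c, c2, 1, ghost=ghost_trans)
        if c3k:
            self.m = [C3k(b, self.c, self.c, 2, shortcut,
                          ghost_inner=ghost_inner, ghost_trans=ghost_trans)
                      for _ in range(n)]
        else:
            self.m = [Bottleneck(b, self.c, self.c, shortcut, k=(3, 3), e=0.5,
                                 ghost=ghost_inner) for _ in range(n)]

    def forward(self, x):
        y = self.cv1(x)
        outs = [ag.narrow(y, 1, 0, self.c), ag.narrow(y, 1, self.c, self.c)]
        for m in self.m:
            outs.append(m(outs[-1]))
        return self.cv2(ag.concat(outs, axis=1))


class SPPF(nn.Module):
    def __init__(self, b: _Builder, c1, c2, k=5, ghost=False):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = b.conv(c1, c_, 1, ghost=ghost)
        self.cv2 = b.conv(c_ * 4, c2, 1, ghost=ghost)
        self.pool = MaxPool2d(k, 1)

    def forward(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(self.pool(y[-1]))
        return self.cv2(ag.concat(y, axis=1))


class Attention(nn.Module):
    """Multi-head self-attention over spatial positions with a depthwise
    positional-encoding branch (position-sensitive attention)."""

    def __init__(self, b: _Builder, dim, num_heads, attn_ratio=0.5):
        super().__init__()
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.key_dim = int(self.head_dim * attn_ratio)
        self.scale = self.key_dim ** -0.5
        h = dim + self.key_dim * num_heads * 2
        self.qkv = b.conv(dim, h, 1, act=False)
        self.proj = b.conv(dim, dim, 1, act=False)
        self.pe = ConvBNAct(dim, dim, 3, groups=dim, act=False, rng=b.rng, dtype=b.dtype)

    def forward(self, x):
        n_, c, hh, ww = x.shape
        npos = hh * ww
        qkv = self.qkv(x)
        qkv = ag.reshape(qkv, (n_, self.num_heads, self.key_dim * 2 + self.head_dim, npos))
        q = ag.narrow(qkv, 2, 0, self.key_dim)
        k = ag.narrow(qkv, 2, self.key_dim, self.key_dim)
        v = ag.narrow(qkv, 2, 2 * self.key_dim, self.head_dim)
        attn = ag.mul(ag.matmul(ag.transpose(q, (0, 1, 3, 2)), k), self.scale)
        attn = ag.softmax(attn, axis=-1)
        out = ag.matmul(v, ag.transpose(attn, (0, 1, 3, 2)))
        out = ag.reshape(out, (n_, c, hh, ww))
        vmap = ag.reshape(v, (n_, c, hh, ww))
        out = ag.add(out, self.pe(vmap))
        return self.proj(out)


class PSABlock(nn.Module):
    def __init__(self, b: _Builder, c, attn_ratio=0.5, num_heads=4):
        super().__init__()
        self.attn = Attention(b, c, num_heads, attn_ratio)
        self.ffn = nn.Sequential(b.conv(c, c * 2, 1), b.conv(c * 2, c, 1, act=False))

    def forward(self, x):
        x = ag.add(x, self.attn(x))
        return ag.add(x, self.ffn(x))


class C2PSA(nn.Module):
    def __init__(self, b: _Builder, c1, c2, n=1, e=0.5, ghost=False):
        super().__init__()
        assert c1 == c2
        self.c = int(c1 * e)
        self.cv1 = b.conv(c1, 2 * self.c, 1, ghost=ghost)
        self.cv2 = b.conv(2 * self.c, c1, 1, ghost=ghost)
        self.m = nn.Sequential(*[PSABlock(b, self.c, 0.5, max(1, self.c // 64))
                                 for _ in range(n)])

    def forward(self, x):
        y = self.cv1(x)
        a = ag.narrow(y, 1, 0, self.c)
        bpart = ag.narrow(y, 1, self.c, self.c)
        bpart = self.m(bpart)
        return self.cv2(ag.concat([a, bpart], axis=1))


class DFL(nn.Module):
    """Distribution-focal decode: softmax over bins -> expected distance."""

    def __init__(self, reg_max: int):
        super().__init__()
        self.reg_max = reg_max

    def forward(self, x):
        # x: (N, 4*reg_max, A) -> (N, 4, A)
        n_, _, a = x.shape
        x = ag.reshape(x, (n_, 4, self.reg_max, a))
        p = ag.softmax(x, axis=2)
        bins = np.arange(self.reg_max, dtype=p.data.dtype).reshape(1, 1, self.reg_max, 1)
        return ag.sum_(ag.mul(p, bins), axis=2)


class Detect(nn.Module):
    """Decoupled anchor-free head over three feature levels."""

    def __init__(self, b: _Builder, nc, ch, reg_max=16, input_size=640):
        super().__init__()
        self.nc = nc
        self.reg_max = reg_max
        self.strides = (8, 16, 32)
        c2 = max(16, ch[0] // 4, reg_max * 4)
        c3 = max(ch[0], min(nc, 100))
        self.cv2 = [
            nn.Sequential(b.conv(x, c2, 3), b.conv(c2, c2, 3),
                          Conv2d(c2, 4 * reg_max, 1, bias=True, rng=b.rng, dtype=b.dtype))
            for x in ch
        ]
        self.cv3 = [
            nn.Sequential(
                nn.Sequential(b.conv(x, x, 3, groups=x), b.conv(x, c3, 1)),
                nn.Sequential(b.conv(c3, c3, 3, groups=c3), b.conv(c3, c3, 1)),
                Conv2d(c3, nc, 1, bias=True, rng=b.rng, dtype=b.dtype))
            for x in ch
        ]
        self.dfl = DFL(reg_max)
        # prior-aware bias init stabilizes the first epochs
        for i, s in enumerate(self.strides):
            self.cv2[i][-1].bias.data[:] = 1.0
            self.cv3[i][-1].bias.data[:] = math.log(5 / nc / (input_size / s) ** 2)

    def forward(self, feats):
        return [ag.concat([self.cv2[i](f), self.cv3[i](f)], axis=1)
                for i, f in enumerate(feats)]


def make_anchors(shapes, strides, offset=0.5):
    """Cell-center anchor points (in cell units) and per-anchor strides."""
    points, strs = [], []
    for (h, w), s in zip(shapes, strides):
        gy, gx = np.meshgrid(np.arange(h) + offset, np.arange(w) + offset, indexing="ij")
        points.append(np.stack([gx.ravel(), gy.ravel()], axis=-1))
        strs.append(np.full(h * w, s, dtype=np.float64))
    return np.concatenate(points, axis=0), np.concatenate(strs, axis=0)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class DetectionModel(nn.Module):
    """Backbone + neck + head; structure is fixed, widths come from the config."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        b = _Builder(cfg)
        w1, w2, w3, w4, w5 = cfg.channels()
        n = cfg.repeats(2)
        scope = cfg.ghost_scope
        # which backbone components get ghost convolutions; "deep" keeps the
        # high-resolution stem/early stages and the attention stage dense
        scopes = {
            "deep": {"stage4", "down3", "stage6", "down4", "stage8", "sppf"},
            "bottlenecks": set(),
            "backbone": {"stem", "down1", "stage2", "down2", "stage4", "down3",
                         "stage6", "down4", "stage8", "sppf"},
            "backbone_psa": {"stem", "down1", "stage2", "down2", "stage4", "down3",
                             "stage6", "down4", "stage8", "sppf", "psa"},
        }
        active = scopes[scope] if cfg.repghost else set()
        gh = active.__contains__
        # inner bottleneck convs: ghosted wherever the stage is in scope, and
        # everywhere in the "bottlenecks"-only scope
        def gin(name):
            return cfg.repghost and (scope == "bottlenecks" or name in active)

        # backbone
        self.stem = b.conv(3, w1, 3, 2, ghost=gh("stem"))
        self.down1 = b.conv(w1, w2, 3, 2, ghost=gh("down1"))
        self.stage2 = C3k2(b, w2, w3, n, c3k=False, e=0.25,
                           ghost_inner=gin("stage2"), ghost_trans=gh("stage2"))
        self.down2 = b.conv(w3, w3, 3, 2, ghost=gh("down2"))
        self.stage4 = C3k2(b, w3, w4, n, c3k=False, e=0.25,
                           ghost_inner=gin("stage4"), ghost_trans=gh("stage4"))
        self.down3 = b.conv(w4, w4, 3, 2, ghost=gh("down3"))
        self.stage6 = C3k2(b, w4, w4, n, c3k=True,
                           ghost_inner=gin("stage6"), ghost_trans=gh("stage6"))
        self.down4 = b.conv(w4, w5, 3, 2, ghost=gh("down4"))
        self.stage8 = C3k2(b, w5, w5, n, c3k=True,
                           ghost_inner=gin("stage8"), ghost_trans=gh("stage8"))
        self.sppf = SPPF(b, w5, w5, 5, ghost=gh("sppf"))
        self.psa = C2PSA(b, w5, w5, n, ghost=gh("psa")) if cfg.use_psa else Identity()

        # neck (PAN)
        self.up = nn.Upsample2x()
        self.neck_p4 = C3k2(b, w5 + w4, w4, n, c3k=False)
        self.neck_p3 = C3k2(b, w4 + w4, w3, n, c3k=False)
        self.down_p3 = b.conv(w3, w3, 3, 2)
        self.neck_n4 = C3k2(b, w3 + w4, w4, n, c3k=False)
        self.down_p4 = b.conv(w4, w4, 3, 2)
        self.neck_n5 = C3k2(b, w4 + w5, w5, n, c3k=True)

        att = (lambda: EnSimAM(cfg.ensimam_cfg)) if cfg.ensimam else Identity
        self.att_p4 = att()
        self.att_p3 = att()
        self.att_n4 = att()
        self.att_n5 = att()

        self.head = Detect(b, cfg.num_classes, (w3, w4, w5),
                           reg_max=cfg.reg_max, input_size=cfg.input_size)
        self.strides = self.head.strides

    def forward(self, x):
        x = ag.tensor(x)
        p1 = self.stem(x)
        p2 = self.stage2(self.down1(p1))
        p3 = self.stage4(self.down2(p2))          # stride 8
        p4 = self.stage6(self.down3(p3))          # stride 16
        p5 = self.psa(self.sppf(self.stage8(self.down4(p4))))   # stride 32

        u4 = self.att_p4(self.neck_p4(ag.concat([self.up(p5), p4], axis=1)))
        u3 = self.att_p3(self.neck_p3(ag.concat([self.up(u4), p3], axis=1)))
        d4 = self.att_n4(self.neck_n4(ag.concat([self.down_p3(u3), u4], axis=1)))
        d5 = self.att_n5(self.neck_n5(ag.concat([self.down_p4(d4), p5], axis=1)))
        return self.head([u3, d4, d5])

    def fuse(self):
        """Re-parameterize every ghost block to its single-path form."""
        for m in self.modules():
            if isinstance(m, RepGhostBlock) and m.mode == "training_multibranch":
                m.fuse()
        return self
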