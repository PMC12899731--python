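"""RepGhost: ghost-feature convolution with train-time branches that fuse
into a single inference path.

A conventional convolution producing ``n`` output channels is replaced by a
primary convolution producing only ``m = n / s`` *intrinsic* channels,
followed by cheap depthwise transforms that spawn ``s - 1`` *ghost*
channels per intrinsic one; the output concatenates ``[intrinsic, ghosts]``.
This cuts the multiply–accumulate cost from ``n*c*k^2*h*w`` to
``m*c*k^2*h*w + (s-1)*m*d^2*h*w`` (``k``/``d`` = primary/cheap kernels).

During training each cheap transform may carry parallel branches (the
depthwise conv + a normalization-only shortcut). :meth:`RepGhostBlock.fuse`
folds every batch norm into its convolution and sums same-support branches
into one depthwise kernel, giving an arithmetically equivalent single-path
block for inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.layers import BatchNorm2d, Conv2d, Identity, SiLU

__all__ = ["GhostConfig", "RepGhostBlock", "theoretical_cost", "fuse_conv_bn"]


@dataclass(frozen=True)
class GhostConfig:
    in_channels: int
    out_channels: int
    ratio: int = 2                 # s: ghosts per intrinsic channel (incl. itself)
    primary_kernel: int = 1
    cheap_kernel: int = 3
    stride: int = 1
    use_batchnorm_branches: bool = True
    use_identity_branch: bool = True
    merge: str = "concat"          # 'concat' (default) or 'add'

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1 or self.ratio < 1:
            raise ValueError("channels and ratio must be positive")
        if self.out_channels % self.ratio != 0:
            raise ValueError(
                f"out_channels={self.out_channels} not divisible by ratio={self.ratio}")
        if self.primary_kernel % 2 == 0 or self.cheap_kernel % 2 == 0:
            raise ValueError("kernels must be odd")
        if self.merge not in ("concat", "add"):
            raise ValueError("merge must be 'concat' or 'add'")

    @property
    def intrinsic(self) -> int:
        return self.out_channels // self.ratio


def theoretical_cost(cfg: GhostConfig, h: int, w: int):
    """(ordinary_macs, ghost_macs) at an h x w output grid, exact integers.

    Counts multiply–accumulates of the convolutions only; bias and
    normalization terms are excluded.
    """
    if h < 1 or w < 1:
        raise ValueError("spatial dims must be positive")
    c, n, s = cfg.in_channels, cfg.out_channels, cfg.ratio
    m = cfg.intrinsic
    k, d = cfg.primary_kernel, cfg.cheap_kernel
    ordinary = n * c * k * k * h * w
    ghost = m * c * k * k * h * w + (s - 1) * m * d * d * h * w
    return int(ordinary), int(ghost)


def fuse_conv_bn(weight: np.ndarray, bias, bn: BatchNorm2d):
    """Fold eval-mode batch norm into conv weight/bias."""
    scale, shift = bn.fold_coeffs()
    w = weight * scale[:, None, None, None]
    b = shift if bias is None else bias * scale + shift
    return w, b


class _GhostBranch(nn.Module):
    """One cheap transform: depthwise conv + BN, optionally with a parallel
    normalization-only shortcut (the re-parameterizable extra branch)."""

    def __init__(self, channels, kernel, with_bn_branch, rng, dtype):
        super().__init__()
        self.channels, self.kernel = channels, kernel
        self.dw = Conv2d(channels, channels, kernel, 1, groups=channels, bias=False,
                         rng=rng, dtype=dtype)
        self.bn = BatchNorm2d(channels, dtype=dtype)
        self.shortcut_bn = BatchNorm2d(channels, dtype=dtype) if with_bn_branch else None

    def forward(self, y):
        out = self.bn(self.dw(y))
        if self.shortcut_bn is not None:
            out = ag.add(out, self.shortcut_bn(y))
        return out

    def fused_kernel(self):
        """Collapse all branches into one depthwise (kernel, bias) pair."""
        w, b = fuse_conv_bn(self.dw.weight.data, None, self.bn)
        if self.shortcut_bn is not None:
            scale, shift = self.shortcut_bn.fold_coeffs()
            mid = self.kernel // 2
            w = w.copy()
            w[:, 0, mid, mid] += scale
            b = b + shift
        return w, b


class RepGhostBlock(nn.Module):
    """Ghost convolution block with training/inference structural modes."""

    def __init__(self, cfg: GhostConfig, rng=None, dtype=np.float32, act=True):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.mode = "training_multibranch"
        m = cfg.intrinsic
        self.primary = Conv2d(cfg.in_channels, m, cfg.primary_kernel, cfg.stride,
                              bias=False, rng=rng, dtype=dtype)
        self.primary_bn = BatchNorm2d(m, dtype=dtype)
        with_bn = cfg.use_batchnorm_branches and cfg.use_identity_branch
        self.branches = [
            _GhostBranch(m, cfg.cheap_kernel, with_bn, rng, dtype)
            for _ in range(cfg.ratio - 1)
        ]
        self.act = SiLU() if act else Identity()
        # populated by fuse()
        self.fused_primary = None
        self.fused_cheap = []

    # -- forward -------------------------------------------------------
    def forward(self, x):
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, got {x.shape[1]}")
        if self.mode == "fused_inference":
            y = self.act(self.fused_primary(x))
            ghosts = [self.act(cheap(y)) for cheap in self.fused_cheap]
        else:
            y = self.act(self.primary_bn(self.primary(x)))
            ghosts = [self.act(branch(y)) for branch in self.branches]
        if not ghosts:
            return y
        if self.cfg.merge == "add":
            out = y
            for g in ghosts:
                out = ag.add(out, g)
            return out
        return ag.concat([y] + ghosts, axis=1)

    # -- re-parameterization --------------------------------------------
    def fuse(self):
        """Fold norms and sum parallel branches; idempotent after the first call."""
        if self.mode == "fused_inference":
            warnings.warn("RepGhostBlock already fused; fuse() is a no-op", stacklevel=2)
            return self
        m = self.cfg.intrinsic
        dtype = self.primary.weight.data.dtype
        w, b = fuse_conv_bn(self.primary.weight.data, None, self.primary_bn)
        fused = Conv2d(self.cfg.in_channels, m, self.cfg.primary_kernel,
                       self.cfg.stride, bias=True, dtype=dtype)
        fused.weight.data = w.astype(dtype)
        fused.bias.data = b.astype(dtype)
        self.fused_primary = fused
        self.fused_cheap = []
        for branch in self.branches:
            kw, kb = branch.fused_kernel()
            cheap = Conv2d(m, m, self.cfg.cheap_kernel, 1, groups=m, bias=True, dtype=dtype)
            cheap.weight.data = kw.astype(dtype)
            cheap.bias.data = kb.astype(dtype)
            self.fused_cheap.append(cheap)
        # drop the training-time branches so the fused block is single-path
        del self.primary, self.primary_bn
        self.branches = []
        self.mode = "fused_inference"
        return self
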