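"""EnSimAM: parameter-free three-branch attention for small, dense targets.

The mechanism extends SimAM's energy-based neuron importance with two extra
spatial cues and fuses the three with data-derived (not learned) weights:

* **Global branch** — the SimAM closed form. For each channel with mean
  ``mu`` and variance ``s2``, the inverse minimal energy of a neuron with
  activation ``t`` is ``1/e* = (t - mu)^2 / (4 (s2 + lambda)) + 1/2`` and the
  attention weight is ``sigmoid(1/e*)``.
* **Local branch** — the variance of each 3x3 neighbourhood (fixed divisor
  9), ``sigmoid(alpha * var_3x3)``; flat regions settle at 0.5.
* **Edge branch** — Sobel gradient magnitude ``G = sqrt(Gx^2 + Gy^2)``,
  ``sigmoid(beta * G)``.

Fusion weights come from the channel's spatial L2 norm:
``w_global = ||X|| / (||X|| + eps)``, ``w_local = w_edge = (1 - w_global)/2``,
so they always sum to 1. The final map ``A = w_g A_g + w_l A_l + w_e A_e``
modulates the input multiplicatively (``X * A``). The whole operation has
zero learnable parameters.

Two implementations are provided: a plain-NumPy reference API
(:func:`apply_ensimam` and friends) and an autograd layer
(:class:`EnSimAM`) used inside the detector; they agree to float precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import autograd as ag

__all__ = [
    "EnSimAMConfig", "channel_stats", "global_attention", "local_attention",
    "edge_attention", "fusion_weights", "apply_ensimam", "EnSimAM",
    "SOBEL_X", "SOBEL_Y",
]

SOBEL_X = np.array([[-1.0, 0.0, 1.0],
                    [-2.0, 0.0, 2.0],
                    [-1.0, 0.0, 1.0]])
SOBEL_Y = SOBEL_X.T.copy()


@dataclass(frozen=True)
class EnSimAMConfig:
    """Hyperparameters of the attention. All branches are parameter-free.

    Attributes
    ----------
    lambda_reg:
        Regularization added to the channel variance in the energy closed
        form (SimAM convention, default 1e-4).
    alpha_local, beta_edge:
        Scaling of the local-variance and edge responses before the sigmoid.
    eps_fusion:
        Guard against division by zero in the fusion weights.
    variance_correction:
        "M_minus_1" (sample variance, default) or "M" (population).
    padding_mode:
        Border handling for the 3x3 pooling and Sobel windows.
    fusion_norm:
        "l2" uses the literal spatial L2 norm in the fusion weight; "rms"
        divides it by sqrt(H*W) first, which avoids the saturation of
        w_global toward 1 on anything but tiny maps.
    """

    lambda_reg: float = 1e-4
    alpha_local: float = 1.0
    beta_edge: float = 1.0
    eps_fusion: float = 1e-4
    variance_correction: str = "M_minus_1"
    padding_mode: str = "zero"
    fusion_norm: str = "l2"

    def __post_init__(self):
        for name in ("lambda_reg", "alpha_local", "beta_edge", "eps_fusion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.variance_correction not in ("M_minus_1", "M"):
            raise ValueError("variance_correction must be 'M_minus_1' or 'M'")
        if self.padding_mode not in ("zero", "replicate"):
            raise ValueError("padding_mode must be 'zero' or 'replicate'")
        if self.fusion_norm not in ("l2", "rms"):
            raise ValueError("fusion_norm must be 'l2' or 'rms'")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _check_finite(x: np.ndarray):
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map contains non-finite values")


def _as_batched(x: np.ndarray):
    """Normalize input to (N, C, H, W); return (array, had_batch_axis)."""
    x = np.asarray(x, dtype=np.float64 if x.dtype == np.float64 else np.float32)
    if x.ndim == 3:
        return x[None], False
    if x.ndim == 4:
        return x, True
    raise ValueError(f"expected a CxHxW or NxCxHxW feature map, got ndim={x.ndim}")


def channel_stats(channel: np.ndarray, correction: str = "M_minus_1"):
    """Mean and variance of one 2-D channel over all M = H*W positions.

    A single-element channel with the sample correction has an undefined
    divisor; the variance is defined as 0 in that degenerate case.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0:
        raise ValueError("empty channel")
    _check_finite(channel)
    m = channel.size
    mean = float(channel.mean())
    if correction == "M_minus_1":
        var = float(channel.var(ddof=1)) if m > 1 else 0.0
    elif correction == "M":
        var = float(channel.var(ddof=0))
    else:
        raise ValueError("correction must be 'M_minus_1' or 'M'")
    return mean, var


def _channel_mean_var(x: np.ndarray, correction: str):
    """Vectorized per-(sample, channel) spatial mean and variance."""
    n, c, h, w = x.shape
    m = h * w
    flat = x.reshape(n, c, m)
    mu = flat.mean(axis=-1, keepdims=True)
    ddof = 1 if (correction == "M_minus_1" and m > 1) else 0
    var = flat.var(axis=-1, ddof=ddof, keepdims=True)
    return mu.reshape(n, c, 1, 1), var.reshape(n, c, 1, 1)


def global_attention(x: np.ndarray, cfg: EnSimAMConfig = EnSimAMConfig()) -> np.ndarray:
    """SimAM weights: sigmoid((t-mu)^2 / (4(var+lambda)) + 1/2) per channel."""
    xb, batched = _as_batched(x)
    _check_finite(xb)
    mu, var = _channel_mean_var(xb, cfg.variance_correction)
    inv_energy = (xb - mu) ** 2 / (4.0 * (var + cfg.lambda_reg)) + 0.5
    a = _sigmoid(inv_energy)
    return a if batched else a[0]


def _avg3x3(x: np.ndarray, padding_mode: str) -> np.ndarray:
    """3x3 box filter with fixed divisor 9 on an (N,C,H,W) array."""
    mode = "constant" if padding_mode == "zero" else "edge"
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)), mode=mode)
    out = np.zeros_like(x)
    h, w = x.shape[2], x.shape[3]
    for i in range(3):
        for j in range(3):
            out += xp[:, :, i:i + h, j:j + w]
    return out / 9.0


def local_attention(x: np.ndarray, cfg: EnSimAMConfig = EnSimAMConfig()) -> np.ndarray:
    """Weights from 3x3 local variance: sigmoid(alpha * var_3x3)."""
    xb, batched = _as_batched(x)
    _check_finite(xb)
    mu = _avg3x3(xb, cfg.padding_mode)
    # E[(x - mu)^2] over the same fixed-divisor window == E[x^2] - mu^2
    var = _avg3x3(xb * xb, cfg.padding_mode) - mu ** 2
    var = np.maximum(var, 0.0)
    a = _sigmoid(cfg.alpha_local * var)
    return a if batched else a[0]


def _correlate3x3(x: np.ndarray, kernel: np.ndarray, padding_mode: str) -> np.ndarray:
    mode = "constant" if padding_mode == "zero" else "edge"
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)), mode=mode)
    out = np.zeros_like(x)
    h, w = x.shape[2], x.shape[3]
    for i in range(3):
        for j in range(3):
            if kernel[i, j] != 0:
                out += kernel[i, j] * xp[:, :, i:i + h, j:j + w]
    return out


def edge_attention(x: np.ndarray, cfg: EnSimAMConfig = EnSimAMConfig()) -> np.ndarray:
    """Weights from Sobel gradient magnitude: sigmoid(beta * |grad|)."""
    xb, batched = _as_batched(x)
    _check_finite(xb)
    gx = _correlate3x3(xb, SOBEL_X, cfg.padding_mode)
    gy = _correlate3x3(xb, SOBEL_Y, cfg.padding_mode)
    g = np.sqrt(gx * gx + gy * gy)
    a = _sigmoid(cfg.beta_edge * g)
    return a if batched else a[0]


def fusion_weights(x: np.ndarray, cfg: EnSimAMConfig = EnSimAMConfig()):
    """Per-channel fusion weights (w_global, w_local, w_edge), summing to 1.

    w_global = ||X||2 / (||X||2 + eps) over the channel's spatial positions
    (optionally RMS-normalized); the remainder is split evenly between the
    local and edge branches.
    """
    xb, batched = _as_batched(x)
    _check_finite(xb)
    n, c, h, w = xb.shape
    norm = np.sqrt((xb.astype(np.float64) ** 2).sum(axis=(2, 3)))
    if cfg.fusion_norm == "rms":
        norm = norm / np.sqrt(h * w)
    w_g = norm / (norm + cfg.eps_fusion)
    w_le = (1.0 - w_g) / 2.0
    if not batched:
        w_g, w_le = w_g[0], w_le[0]
    return w_g, w_le, w_le.copy()


def apply_ensimam(x: np.ndarray, cfg: EnSimAMConfig = EnSimAMConfig()) -> np.ndarray:
    """Full attention: fuse the three branch maps and modulate the input.

    Returns ``X * A`` where ``A = w_g*A_global + w_l*A_local + w_e*A_edge``
    with per-channel fusion weights; shape is preserved exactly.
    """
    xb, batched = _as_batched(x)
    _check_finite(xb)
    a_g = global_attention(xb, cfg)
    a_l = local_attention(xb, cfg)
    a_e = edge_attention(xb, cfg)
    if a_g.shape != xb.shape or a_l.shape != xb.shape or a_e.shape != xb.shape:
        raise RuntimeError("internal branch shape mismatch")
    w_g, w_l, w_e = fusion_weights(xb, cfg)
    w_g = w_g[:, :, None, None]
    w_l = w_l[:, :, None, None]
    w_e = w_e[:, :, None, None]
    a = (w_g * a_g + w_l * a_l + w_e * a_e).astype(xb.dtype)
    out = xb * a
    return out if batched else out[0]


class EnSimAM(nn.Module):
    """Autograd layer form of the attention, used at the detector's neck.

    Carries zero learnable parameters; gradients flow through both the
    input and the attention weights derived from it. A small epsilon
    stabilizes the gradient of the edge magnitude at exactly-zero gradient
    locations.
    """

    def __init__(self, cfg: EnSimAMConfig | None = None):
        super().__init__()
        self.cfg = cfg or EnSimAMConfig()

    def forward(self, x):
        cfg = self.cfg
        n, c, h, w = x.shape
        m = h * w
        dtype = x.data.dtype
        mu = ag.mean_(x, axis=(2, 3), keepdims=True)
        d = ag.sub(x, mu)
        var = ag.mean_(ag.mul(d, d), axis=(2, 3), keepdims=True)
        if cfg.variance_correction == "M_minus_1" and m > 1:
            var = ag.mul(var, m / (m - 1))
        inv_energy = ag.add(ag.div(ag.mul(d, d), ag.mul(ag.add(var, cfg.lambda_reg), 4.0)), 0.5)
        a_g = ag.sigmoid(inv_energy)

        box = np.full((c, 1, 3, 3), 1.0 / 9.0, dtype=dtype)
        if cfg.padding_mode == "zero":
            xp = x
            pad = 1
        else:
            xp = ag.pad2d(x, 1, mode="replicate")
            pad = 0
        mu_l = ag.conv2d(xp, box, stride=1, padding=pad, groups=c, count=False)
        x2 = ag.mul(x, x)
        xp2 = x2 if cfg.padding_mode == "zero" else ag.pad2d(x2, 1, mode="replicate")
        ex2 = ag.conv2d(xp2, box, stride=1, padding=pad, groups=c, count=False)
        var_l = ag.relu(ag.sub(ex2, ag.mul(mu_l, mu_l)))
        a_l = ag.sigmoid(ag.mul(var_l, cfg.alpha_local))

        kx = np.broadcast_to(SOBEL_X.astype(dtype), (c, 1, 3, 3)).copy()
        ky = np.broadcast_to(SOBEL_Y.astype(dtype), (c, 1, 3, 3)).copy()
        gx = ag.conv2d(xp, kx, stride=1, padding=pad, groups=c, count=False)
        gy = ag.conv2d(xp, ky, stride=1, padding=pad, groups=c, count=False)
        g = ag.sqrt(ag.add(ag.add(ag.mul(gx, gx), ag.mul(gy, gy)), 1e-12))
        a_e = ag.sigmoid(ag.mul(g, cfg.beta_edge))

        norm = ag.sqrt(ag.add(ag.sum_(ag.mul(x, x), axis=(2, 3), keepdims=True), 1e-24))
        if cfg.fusion_norm == "rms":
            norm = ag.mul(norm, 1.0 / np.sqrt(m))
        w_g = ag.div(norm, ag.add(norm, cfg.eps_fusion))
        w_le = ag.mul(ag.sub(1.0, w_g), 0.5)
        a = ag.add(ag.add(ag.mul(w_g, a_g), ag.mul(w_le, a_l)), ag.mul(w_le, a_e))
        return ag.mul(x, a)
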