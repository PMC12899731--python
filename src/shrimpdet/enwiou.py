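"""EnWIoU: orientation- and aspect-aware weighted IoU loss for small boxes.

Built on top of the WIoU idea of non-monotonic gradient-gain focusing:

* ``IoU`` — standard intersection over union of center-format boxes.
* Outlier degree ``beta = d / C``: distance between the two box centers
  divided by the diagonal of their minimum enclosing box (always in [0, 1)).
* Focusing gain ``r = beta / (delta * alpha**(beta - delta))`` with
  hyperparameters ``alpha`` (> 1) and ``delta``; ``r`` is treated as a
  constant multiplier per step — no gradient flows through it.
* Orientation modulation ``gamma``: if either box is elongated (aspect
  ratio above ``tau_aspect``), a matching principal direction scales the
  loss by ``1 - eta`` and a mismatch by ``1 + eta``; otherwise 1.

The loss is ``clamp(r * (1 - IoU) * gamma, 0, 1)``. Defaults follow the
published operating point: ``tau_aspect = 2.0``, ``eta = 0.1``,
``alpha = 1.9``, ``delta = 3``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nn import autograd as ag

__all__ = [
    "EnWIoUConfig", "LossBreakdown", "iou_xywh", "outlier_degree",
    "focusing_gain", "orientation_modulation", "enwiou", "enwiou_batch",
    "enwiou_loss_xyxy",
]


@dataclass(frozen=True)
class EnWIoUConfig:
    alpha_focus: float = 1.9      # focusing base, must exceed 1
    delta_focus: float = 3.0      # focusing pivot: r = 1 at beta = delta
    tau_aspect: float = 2.0       # aspect threshold flagging elongated boxes
    eta: float = 0.1              # orientation penalty intensity
    reduction: str = "mean"
    beta_squared: bool = False    # literal (d/C)^2 reading, for sensitivity tests
    r_min: float = 0.0            # optional floor on the focusing gain

    clamp_lo: float = 0.0
    clamp_hi: float = 1.0

    def __post_init__(self):
        if self.alpha_focus <= 1.0:
            raise ValueError("alpha_focus must be > 1")
        if self.delta_focus <= 0:
            raise ValueError("delta_focus must be > 0")
        if self.tau_aspect < 1.0:
            raise ValueError("tau_aspect must be >= 1")
        if not 0.0 <= self.eta < 1.0:
            raise ValueError("eta must lie in [0, 1)")
        if self.reduction not in ("mean", "sum", "none"):
            raise ValueError("reduction must be mean|sum|none")


@dataclass(frozen=True)
class LossBreakdown:
    """All intermediate factors of one EnWIoU evaluation."""

    iou: float
    l_iou: float
    beta_outlier: float
    r_gain: float
    gamma: float
    loss: float


def _validate_box(b) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    if b.shape != (4,):
        raise ValueError("box must be (cx, cy, w, h)")
    if not np.all(np.isfinite(b)):
        raise ValueError("box has non-finite coordinates")
    if b[2] <= 0 or b[3] <= 0:
        raise ValueError("box width and height must be positive")
    return b


def _to_corners(b: np.ndarray):
    cx, cy, w, h = b
    return cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2


def iou_xywh(a, b) -> float:
    """Intersection over union of two center-format axis-aligned boxes."""
    a, b = _validate_box(a), _validate_box(b)
    ax1, ay1, ax2, ay2 = _to_corners(a)
    bx1, by1, bx2, by2 = _to_corners(b)
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = a[2] * a[3] + b[2] * b[3] - inter
    return float(inter / union)


def outlier_degree(pred, gt, cfg: EnWIoUConfig = EnWIoUConfig()) -> float:
    """beta = center distance / enclosing-box diagonal (squared if configured)."""
    pred, gt = _validate_box(pred), _validate_box(gt)
    px1, py1, px2, py2 = _to_corners(pred)
    gx1, gy1, gx2, gy2 = _to_corners(gt)
    wg = max(px2, gx2) - min(px1, gx1)
    hg = max(py2, gy2) - min(py1, gy1)
    d2 = (gt[0] - pred[0]) ** 2 + (gt[1] - pred[1]) ** 2
    c2 = wg * wg + hg * hg
    ratio2 = d2 / c2
    return float(ratio2 if cfg.beta_squared else np.sqrt(ratio2))


def focusing_gain(beta: float, cfg: EnWIoUConfig = EnWIoUConfig()) -> float:
    """Non-monotonic gain r = beta / (delta * alpha**(beta - delta)).

    r = 1 exactly at beta = delta and r -> 0 as beta -> 0, down-weighting
    both the best and the worst anchors in favour of ordinary ones.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    a, d = cfg.alpha_focus, cfg.delta_focus
    r = beta / (d * a ** (beta - d))
    return float(max(r, cfg.r_min))


def _aspect(w: float, h: float) -> float:
    return max(w, h) / min(w, h)


def orientation_modulation(pred, gt, cfg: EnWIoUConfig = EnWIoUConfig()):
    """Return (gamma, i_orient, is_elongated).

    gamma = 1 - eta for an elongated pair with consistent principal
    direction, 1 + eta for an inconsistent one, 1 if neither box is
    elongated. Squares (w == h) count as "tall".
    """
    pred, gt = _validate_box(pred), _validate_box(gt)
    rp = _aspect(pred[2], pred[3])
    rg = _aspect(gt[2], gt[3])
    elongated = max(rp, rg) > cfg.tau_aspect
    wide_p = pred[2] > pred[3]
    wide_g = gt[2] > gt[3]
    i_orient = 1 if wide_p == wide_g else 0
    if not elongated:
        gamma = 1.0
    elif i_orient:
        gamma = 1.0 - cfg.eta
    else:
        gamma = 1.0 + cfg.eta
    return gamma, i_orient, elongated


def enwiou(pred, gt, cfg: EnWIoUConfig = EnWIoUConfig()) -> LossBreakdown:
    """Full scalar loss with its breakdown; loss = clamp(r * (1-IoU) * gamma, 0, 1)."""
    iou = iou_xywh(pred, gt)
    l_iou = 1.0 - iou
    beta = outlier_degree(pred, gt, cfg)
    r = focusing_gain(beta, cfg)
    gamma, _, _ = orientation_modulation(pred, gt, cfg)
    loss = float(np.clip(r * l_iou * gamma, cfg.clamp_lo, cfg.clamp_hi))
    return LossBreakdown(iou=iou, l_iou=l_iou, beta_outlier=beta,
                         r_gain=r, gamma=gamma, loss=loss)


def enwiou_batch(preds, gts, cfg: EnWIoUConfig = EnWIoUConfig()):
    """Reduce the loss over matched prediction/ground-truth box lists."""
    preds, gts = list(preds), list(gts)
    if len(preds) != len(gts):
        raise ValueError(f"length mismatch: {len(preds)} predictions vs {len(gts)} targets")
    if not preds:
        warnings.warn("enwiou_batch called with no box pairs; returning 0", stacklevel=2)
        return 0.0 if cfg.reduction != "none" else np.zeros(0)
    losses = np.array([enwiou(p, g, cfg).loss for p, g in zip(preds, gts)])
    if cfg.reduction == "mean":
        return float(losses.mean())
    if cfg.reduction == "sum":
        return float(losses.sum())
    return losses


# ---------------------------------------------------------------------------
# differentiable path used by the detector's training loop
# ---------------------------------------------------------------------------

def _pairwise_weights(pred_xyxy: np.ndarray, gt_xyxy: np.ndarray, cfg: EnWIoUConfig):
    """Detached per-pair weight r * gamma computed from corner-format arrays."""
    pw = pred_xyxy[:, 2] - pred_xyxy[:, 0]
    ph = pred_xyxy[:, 3] - pred_xyxy[:, 1]
    gw = gt_xyxy[:, 2] - gt_xyxy[:, 0]
    gh = gt_xyxy[:, 3] - gt_xyxy[:, 1]
    pcx = (pred_xyxy[:, 0] + pred_xyxy[:, 2]) / 2
    pcy = (pred_xyxy[:, 1] + pred_xyxy[:, 3]) / 2
    gcx = (gt_xyxy[:, 0] + gt_xyxy[:, 2]) / 2
    gcy = (gt_xyxy[:, 1] + gt_xyxy[:, 3]) / 2
    wg = np.maximum(pred_xyxy[:, 2], gt_xyxy[:, 2]) - np.minimum(pred_xyxy[:, 0], gt_xyxy[:, 0])
    hg = np.maximum(pred_xyxy[:, 3], gt_xyxy[:, 3]) - np.minimum(pred_xyxy[:, 1], gt_xyxy[:, 1])
    ratio2 = ((gcx - pcx) ** 2 + (gcy - pcy) ** 2) / np.maximum(wg ** 2 + hg ** 2, 1e-12)
    beta = ratio2 if cfg.beta_squared else np.sqrt(ratio2)
    r = np.maximum(beta / (cfg.delta_focus * cfg.alpha_focus ** (beta - cfg.delta_focus)),
                   cfg.r_min)
    eps = 1e-9
    rp = np.maximum(pw, ph) / np.maximum(np.minimum(pw, ph), eps)
    rg = np.maximum(gw, gh) / np.maximum(np.minimum(gw, gh), eps)
    elong = np.maximum(rp, rg) > cfg.tau_aspect
    consistent = (pw > ph) == (gw > gh)
    gamma = np.where(elong, np.where(consistent, 1.0 - cfg.eta, 1.0 + cfg.eta), 1.0)
    return r * gamma


def enwiou_loss_xyxy(pred, gt_xyxy: np.ndarray, cfg: EnWIoUConfig = EnWIoUConfig()):
    """Differentiable batched loss on corner-format boxes.

    ``pred`` is an autograd Tensor of shape (N, 4) in (x1, y1, x2, y2);
    ``gt_xyxy`` is a constant array of the same shape. The focusing gain and
    orientation factor are computed from detached values (WIoU convention),
    so gradients flow only through the IoU term.
    """
    if gt_xyxy.shape[0] == 0:
        return ag.tensor(np.zeros((), dtype=np.float32))
    w = _pairwise_weights(pred.data.astype(np.float64), gt_xyxy.astype(np.float64), cfg)
    w = w.astype(pred.data.dtype)
    px1 = ag.narrow(pred, 1, 0, 1)
    py1 = ag.narrow(pred, 1, 1, 1)
    px2 = ag.narrow(pred, 1, 2, 1)
    py2 = ag.narrow(pred, 1, 3, 1)
    g = gt_xyxy.astype(pred.data.dtype)
    gx1, gy1, gx2, gy2 = (g[:, i:i + 1] for i in range(4))
    # max(a, c) = a + relu(c - a); min(a, c) = a - relu(a - c) for constant c
    ix1 = ag.add(px1, ag.relu(ag.sub(gx1, px1)))
    iy1 = ag.add(py1, ag.relu(ag.sub(gy1, py1)))
    ix2 = ag.sub(px2, ag.relu(ag.sub(px2, gx2)))
    iy2 = ag.sub(py2, ag.relu(ag.sub(py2, gy2)))
    iw = ag.relu(ag.sub(ix2, ix1))
    ih = ag.relu(ag.sub(iy2, iy1))
    inter = ag.mul(iw, ih)
    area_p = ag.mul(ag.relu(ag.sub(px2, px1)), ag.relu(ag.sub(py2, py1)))
    area_g = (g[:, 2:3] - g[:, 0:1]) * (g[:, 3:4] - g[:, 1:2])
    union = ag.add(ag.sub(ag.add(area_p, area_g), inter), 1e-9)
    iou = ag.div(inter, union)
    l_iou = ag.sub(1.0, iou)
    per_pair = ag.clip(ag.mul(l_iou, w[:, None]), cfg.clamp_lo, cfg.clamp_hi)
    if cfg.reduction == "sum":
        return ag.sum_(per_pair)
    if cfg.reduction == "none":
        return per_pair
    return ag.mean_(per_pair)
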