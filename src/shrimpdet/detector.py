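"""Training and inference for the residual-feed detector.

Ties the architecture to its supervision: a task-aligned label assigner
matches grid anchors to ground-truth boxes, the composite loss combines
confidence BCE, class cross-entropy and the EnWIoU localization term
(``total = l1*obj + l2*cls + l3*loc``), and prediction decodes the
distribution-focal head output, thresholds confidences and applies
class-aware greedy NMS.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .architecture import (DetectionModel, ModelConfig, baseline_config,
                           make_anchors, shrimp_config, tiny_config)
from .ensimam import EnSimAMConfig
from .enwiou import EnWIoUConfig, enwiou_loss_xyxy
from .nn import Adam
from .nn import autograd as ag

__all__ = [
    "Detection", "TrainConfig", "build_model", "compute_losses", "train",
    "predict", "nms", "decode_predictions", "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class Detection:
    """One predicted object: center-format pixel box, confidence, class."""

    box: tuple            # (cx, cy, w, h) in pixels
    score: float
    class_id: int


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 5e-3
    optimizer: str = "adam"
    seed: int = 0
    device: str = "cpu"
    weight_decay: float = 0.0
    use_enwiou: bool = True        # ablation switch: False -> plain 1-IoU
    enwiou: EnWIoUConfig = dataclasses.field(default_factory=EnWIoUConfig)

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")


def build_model(cfg: ModelConfig) -> DetectionModel:
    """Assemble a detector from its config (see :func:`shrimp_config`,
    :func:`baseline_config`, :func:`tiny_config` for the stock variants)."""
    return DetectionModel(cfg)


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def _flatten_levels(feats, cfg: ModelConfig):
    """Concatenate per-level raw maps to (B, C, A) plus anchor geometry."""
    shapes = [(f.shape[2], f.shape[3]) for f in feats]
    flat = ag.concat([ag.reshape(f, (f.shape[0], f.shape[1], f.shape[2] * f.shape[3]))
                      for f in feats], axis=2)
    anchors, strides = make_anchors(shapes, (8, 16, 32))
    return flat, anchors, strides


def decode_predictions(feats, cfg: ModelConfig):
    """Decode raw head maps into pixel boxes and class logits.

    Returns (boxes_xyxy Tensor (B, A, 4), cls_logits Tensor (B, nc, A),
    anchors (A, 2) in cells, strides (A,)).
    """
    from .architecture import DFL
    rm = cfg.reg_max
    flat, anchors, strides = _flatten_levels(feats, cfg)
    box_raw = ag.narrow(flat, 1, 0, 4 * rm)
    cls_logits = ag.narrow(flat, 1, 4 * rm, cfg.num_classes)
    dist = DFL(rm)(box_raw)                      # (B, 4, A), cell units
    dt = dist.data.dtype
    ax = anchors[:, 0].astype(dt)[None, :]
    ay = anchors[:, 1].astype(dt)[None, :]
    s = strides.astype(dt)[None, :]
    l = ag.reshape(ag.narrow(dist, 1, 0, 1), (dist.shape[0], dist.shape[2]))
    t = ag.reshape(ag.narrow(dist, 1, 1, 1), (dist.shape[0], dist.shape[2]))
    r = ag.reshape(ag.narrow(dist, 1, 2, 1), (dist.shape[0], dist.shape[2]))
    b = ag.reshape(ag.narrow(dist, 1, 3, 1), (dist.shape[0], dist.shape[2]))
    x1 = ag.mul(ag.sub(ax, l), s)
    y1 = ag.mul(ag.sub(ay, t), s)
    x2 = ag.mul(ag.add(ax, r), s)
    y2 = ag.mul(ag.add(ay, b), s)
    boxes = ag.concat([ag.reshape(v, (v.shape[0], v.shape[1], 1)) for v in (x1, y1, x2, y2)],
                      axis=2)                    # (B, A, 4)
    return boxes, cls_logits, anchors, strides


# ---------------------------------------------------------------------------
# task-aligned assignment
# ---------------------------------------------------------------------------

def _iou_matrix(gt: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """IoU between (M,4) gt and (A,4) predicted xyxy boxes -> (M, A)."""
    ix1 = np.maximum(gt[:, None, 0], pred[None, :, 0])
    iy1 = np.maximum(gt[:, None, 1], pred[None, :, 1])
    ix2 = np.minimum(gt[:, None, 2], pred[None, :, 2])
    iy2 = np.minimum(gt[:, None, 3], pred[None, :, 3])
    inter = np.clip(ix2 - ix1, 0, None) * np.clip(iy2 - iy1, 0, None)
    ag_ = np.clip(gt[:, 2] - gt[:, 0], 0, None) * np.clip(gt[:, 3] - gt[:, 1], 0, None)
    ap = np.clip(pred[:, 2] - pred[:, 0], 0, None) * np.clip(pred[:, 3] - pred[:, 1], 0, None)
    return inter / np.maximum(ag_[:, None] + ap[None, :] - inter, 1e-9)


def assign_targets(boxes_xyxy: np.ndarray, scores: np.ndarray, anchors_px: np.ndarray,
                   gt_cls: np.ndarray, gt_xyxy: np.ndarray,
                   topk: int = 10, alpha: float = 0.5, beta: float = 6.0):
    """Task-aligned one-image assignment (detached NumPy).

    Candidates are anchors whose center lies inside a gt box; per gt the
    top-k by ``score^alpha * IoU^beta`` become positives, conflicts resolved
    by higher IoU. Returns (pos_anchor_idx, pos_gt_idx, target_scores (A,)).
    """
    a = boxes_xyxy.shape[0]
    if gt_xyxy.shape[0] == 0:
        return (np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64),
                np.zeros(a, dtype=np.float64))
    inside = ((anchors_px[None, :, 0] > gt_xyxy[:, 0:1])
              & (anchors_px[None, :, 0] < gt_xyxy[:, 2:3])
              & (anchors_px[None, :, 1] > gt_xyxy[:, 1:2])
              & (anchors_px[None, :, 1] < gt_xyxy[:, 3:4]))
    iou = _iou_matrix(gt_xyxy, boxes_xyxy)
    cls_score = scores[gt_cls, :]                       # (M, A)
    align = (cls_score ** alpha) * (iou ** beta)
    align = np.where(inside, align, 0.0)
    m = gt_xyxy.shape[0]
    mask = np.zeros((m, a), dtype=bool)
    k = min(topk, a)
    top = np.argpartition(-align, k - 1, axis=1)[:, :k]
    rows = np.repeat(np.arange(m), k)
    cand = align[rows, top.ravel()] > 0
    mask[rows[cand], top.ravel()[cand]] = True
    # an anchor claimed by several gts goes to the one it overlaps most
    multi = mask.sum(axis=0) > 1
    if multi.any():
        best = iou.argmax(axis=0)
        keep = np.zeros_like(mask)
        keep[best[multi], np.where(multi)[0]] = True
        mask[:, multi] = keep[:, multi]
    pos_gt, pos_anchor = np.where(mask)
    # normalized confidence target per positive (task-aligned convention)
    t_scores = np.zeros(a, dtype=np.float64)
    if pos_anchor.size:
        amax = np.where(mask, align, 0).max(axis=1)
        imax = np.where(mask, iou, 0).max(axis=1)
        t = align[pos_gt, pos_anchor] / np.maximum(amax[pos_gt], 1e-9) * imax[pos_gt]
        t_scores[pos_anchor] = t
    return pos_anchor.astype(np.int64), pos_gt.astype(np.int64), t_scores


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _bce_with_logits(x, target: np.ndarray):
    """Elementwise stable binary cross-entropy on logits (Tensor x)."""
    absx = ag.add(ag.relu(x), ag.relu(ag.neg(x)))
    return ag.add(ag.sub(ag.relu(x), ag.mul(x, target)),
                  ag.log(ag.add(ag.exp(ag.neg(absx)), 1.0)))


def compute_losses(preds, targets, cfg: ModelConfig, tc: TrainConfig | None = None):
    """Composite detection loss on one batch.

    Parameters
    ----------
    preds:
        Raw head output (list of per-level Tensors) from the model forward.
    targets:
        Per-image list of (class_ids (M,), boxes_xyxy_px (M,4)) arrays.
    cfg, tc:
        Model config (for loss weights / classes) and train config (for the
        EnWIoU hyperparameters and the plain-IoU ablation switch).

    Returns (obj, cls, loc, total) as autograd Tensors; ``total`` carries
    the lambda-weighted sum.
    """
    tc = tc or TrainConfig()
    boxes, cls_logits, anchors, strides = decode_predictions(preds, cfg)
    bsz, a = boxes.shape[0], boxes.shape[1]
    nc = cfg.num_classes
    anchors_px = anchors * strides[:, None]
    scores_np = 1.0 / (1.0 + np.exp(-cls_logits.data.astype(np.float64)))

    tgt_matrix = np.zeros((bsz, nc, a), dtype=boxes.data.dtype)
    pos_rows, pos_gt_boxes, pos_weights = [], [], []
    for i, (gcls, gbox) in enumerate(targets):
        gcls = np.asarray(gcls, dtype=np.int64)
        gbox = np.asarray(gbox, dtype=np.float64).reshape(-1, 4)
        pa, pg, ts = assign_targets(boxes.data[i].astype(np.float64), scores_np[i],
                                    anchors_px, gcls, gbox)
        if pa.size:
            tgt_matrix[i, gcls[pg], pa] = ts[pa]
            pos_rows.append(i * a + pa)
            pos_gt_boxes.append(gbox[pg])
            pos_weights.append((i, pa, gcls[pg]))

    bce = _bce_with_logits(cls_logits, tgt_matrix)
    norm = max(float(tgt_matrix.sum()), 1.0)
    obj = ag.div(ag.sum_(bce), norm)

    if pos_rows:
        rows = np.concatenate(pos_rows)
        gt_all = np.concatenate(pos_gt_boxes)
        flat_boxes = ag.reshape(boxes, (bsz * a, 4))
        pos_boxes = ag.index_select(flat_boxes, rows, axis=0)
        ewc = tc.enwiou if tc.use_enwiou else dataclasses.replace(
            tc.enwiou, eta=1e-9, r_min=1.0, delta_focus=1.0, alpha_focus=1.0 + 1e-9)
        loc = enwiou_loss_xyxy(pos_boxes, gt_all, ewc)
        if nc > 1:
            # cross-entropy over classes at the positive anchors
            logits_t = ag.transpose(cls_logits, (0, 2, 1))        # (B, A, nc)
            logits_flat = ag.reshape(logits_t, (bsz * a, nc))
            pos_logits = ag.index_select(logits_flat, rows, axis=0)
            logp = ag.log(ag.add(ag.softmax(pos_logits, axis=1), 1e-12))
            onehot = np.zeros((rows.size, nc), dtype=boxes.data.dtype)
            col = np.concatenate([c for (_, _, c) in pos_weights])
            onehot[np.arange(rows.size), col] = 1.0
            cls = ag.neg(ag.mean_(ag.sum_(ag.mul(logp, onehot), axis=1)))
        else:
            cls = ag.tensor(np.zeros((), dtype=boxes.data.dtype))
    else:
        loc = ag.tensor(np.zeros((), dtype=boxes.data.dtype))
        cls = ag.tensor(np.zeros((), dtype=boxes.data.dtype))

    l1, l2, l3 = cfg.loss_weights
    total = ag.add(ag.add(ag.mul(obj, l1), ag.mul(cls, l2)), ag.mul(loc, l3))
    if not np.isfinite(total.data):
        raise FloatingPointError("non-finite training loss")
    return obj, cls, loc, total


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _sample_to_arrays(sample, input_size):
    """ImageSample (HWC uint8 + normalized labels) -> (CHW float, cls, xyxy px)."""
    img = np.asarray(sample.image, dtype=np.float32) / 255.0
    h, w = img.shape[:2]
    if (h, w) != (input_size, input_size):
        from PIL import Image
        img = np.asarray(
            Image.fromarray(sample.image).resize((input_size, input_size), Image.BILINEAR),
            dtype=np.float32) / 255.0
    chw = img.transpose(2, 0, 1)
    labels = np.asarray(sample.labels, dtype=np.float64).reshape(-1, 5)
    cls = labels[:, 0].astype(np.int64)
    cx, cy, bw, bh = (labels[:, i] * input_size for i in range(1, 5))
    xyxy = np.stack([cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2], axis=1)
    return chw, cls, xyxy


def train(model: DetectionModel, dataset, tc: TrainConfig, val_set=None,
          eval_every: int = 0, verbose: bool = False):
    """Seeded training loop: forward, composite loss, backward, Adam step.

    ``history`` holds one record per epoch with the mean obj/cls/loc/total
    losses, and validation mAP@0.5 when a validation set is supplied
    (computed every ``eval_every`` epochs and at the last epoch).
    """
    if not dataset:
        raise ValueError("empty training dataset")
    cfg = model.cfg
    rng = np.random.default_rng(tc.seed)
    data = [_sample_to_arrays(s, cfg.input_size) for s in dataset]
    opt = Adam(model.parameters(), lr=tc.learning_rate, weight_decay=tc.weight_decay)
    history = []
    model.train()
    for epoch in range(tc.epochs):
        order = rng.permutation(len(data))
        sums = np.zeros(4)
        nb = 0
        for start in range(0, len(data), tc.batch_size):
            idx = order[start:start + tc.batch_size]
            imgs = np.stack([data[i][0] for i in idx])
            targets = [(data[i][1], data[i][2]) for i in idx]
            preds = model(imgs)
            obj, cls, loc, total = compute_losses(preds, targets, cfg, tc)
            opt.zero_grad()
            total.backward()
            opt.step()
            sums += [float(obj.data), float(cls.data), float(loc.data), float(total.data)]
            nb += 1
        rec = {"epoch": epoch, "obj": sums[0] / nb, "cls": sums[1] / nb,
               "loc": sums[2] / nb, "total": sums[3] / nb}
        if val_set is not None and (
                epoch == tc.epochs - 1 or (eval_every and (epoch + 1) % eval_every == 0)):
            rec["val_map50"] = _quick_map50(model, val_set)
            model.train()
        history.append(rec)
        if verbose:
            print(f"epoch {epoch:3d}  " + "  ".join(
                f"{k}={v:.4f}" for k, v in rec.items() if k != "epoch"))
    model.eval()
    return model, history


def _quick_map50(model, samples, conf=0.01):
    from .evalmetrics import map_metrics
    model.eval()
    dets, gts = [], []
    for s in samples:
        dets.append(predict(model, s.image, conf=conf))
        labels = np.asarray(s.labels, dtype=np.float64).reshape(-1, 5)
        h, w = np.asarray(s.image).shape[:2]
        boxes = [(c[1] * w, c[2] * h, c[3] * w, c[4] * h) for c in labels]
        gts.append(list(zip(labels[:, 0].astype(int), boxes)))
    return map_metrics(dets, gts)[0]


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _box_iou_xyxy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return _iou_matrix(a.reshape(-1, 4), b.reshape(-1, 4))


def nms(dets, iou_thr: float):
    """Greedy score-descending suppression, class-aware."""
    out = []
    by_class = {}
    for d in dets:
        by_class.setdefault(d.class_id, []).append(d)
    for cls_dets in by_class.values():
        cls_dets = sorted(cls_dets, key=lambda d: -d.score)
        kept = []
        for d in cls_dets:
            cx, cy, w, h = d.box
            bb = np.array([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2])
            ok = True
            for kd in kept:
                kcx, kcy, kw, kh = kd.box
                kb = np.array([kcx - kw / 2, kcy - kh / 2, kcx + kw / 2, kcy + kh / 2])
                if _box_iou_xyxy(bb, kb)[0, 0] > iou_thr:
                    ok = False
                    break
            if ok:
                kept.append(d)
        out.extend(kept)
    return sorted(out, key=lambda d: -d.score)


def _letterbox(img: np.ndarray, size: int):
    from PIL import Image
    h, w = img.shape[:2]
    scale = min(size / w, size / h)
    nw, nh = max(1, int(round(w * scale))), max(1, int(round(h * scale)))
    resized = np.asarray(Image.fromarray(img).resize((nw, nh), Image.BILINEAR))
    canvas = np.full((size, size, 3), 114, dtype=np.uint8)
    px, py = (size - nw) // 2, (size - nh) // 2
    canvas[py:py + nh, px:px + nw] = resized
    return canvas, scale, px, py


def predict(model: DetectionModel, image, conf: float | None = None,
            iou: float | None = None):
    """Run one image through the (eval-mode) model and return Detections.

    Any input size is accepted; the image is letterboxed to the model's
    square input and boxes are mapped back to original pixel coordinates.
    """
    cfg = model.cfg
    conf = cfg.nms_conf if conf is None else conf
    iou = cfg.nms_iou if iou is None else iou
    img = np.asarray(image)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    h0, w0 = img.shape[:2]
    canvas, scale, px, py = _letterbox(img.astype(np.uint8), cfg.input_size)
    x = (canvas.astype(np.float32) / 255.0).transpose(2, 0, 1)[None]
    model.eval()
    feats = model(x)
    boxes, cls_logits, _, _ = decode_predictions(feats, cfg)
    b = boxes.data[0]
    scores = 1.0 / (1.0 + np.exp(-cls_logits.data[0]))          # (nc, A)
    cls_id = scores.argmax(axis=0)
    best = scores.max(axis=0)
    keep = best >= conf
    dets = []
    for bi, s, c in zip(b[keep], best[keep], cls_id[keep]):
        x1 = (bi[0] - px) / scale
        y1 = (bi[1] - py) / scale
        x2 = (bi[2] - px) / scale
        y2 = (bi[3] - py) / scale
        x1, x2 = np.clip([x1, x2], 0, w0)
        y1, y2 = np.clip([y1, y2], 0, h0)
        if x2 - x1 <= 0 or y2 - y1 <= 0:
            continue
        dets.append(Detection(box=((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1),
                              score=float(s), class_id=int(c)))
    return nms(dets, iou)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def _config_to_dict(cfg: ModelConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["ensimam_cfg"] = dataclasses.asdict(cfg.ensimam_cfg)
    return d


def _config_from_dict(d: dict) -> ModelConfig:
    d = dict(d)
    d["ensimam_cfg"] = EnSimAMConfig(**d["ensimam_cfg"])
    d["loss_weights"] = tuple(d["loss_weights"])
    return ModelConfig(**d)


def save_checkpoint(model: DetectionModel, path, fused: bool = False):
    state = model.state_dict()
    meta = json.dumps({"config": _config_to_dict(model.cfg), "fused": fused})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> DetectionModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    model = DetectionModel(_config_from_dict(meta["config"]))
    if meta.get("fused"):
        model.fuse()
    model.load_state_dict(state)
    return model
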