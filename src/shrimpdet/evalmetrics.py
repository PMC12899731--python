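"""Detection evaluation and model complexity profiling.

Implements the standard mAP protocol (greedy score-ordered matching, one
match per ground truth, 101-point interpolated AP in the COCO convention),
precision/recall at the max-F1 confidence, a confusion matrix with a
background row/column, and hardware-independent complexity accounting
(learnable parameter count; GFLOPs as 2 x conv/linear multiply-accumulates
at a stated input size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nn import mac_counter

__all__ = [
    "PRData", "ComplexityReport", "match_detections", "average_precision",
    "ap_all_point", "map_metrics", "confusion_matrix", "count_params",
    "count_flops", "complexity_report",
]


@dataclass
class PRData:
    """Score-sorted match flags and ground-truth count for one class."""

    scores: np.ndarray      # descending
    is_tp: np.ndarray       # bool, aligned with scores
    n_gt: int


def _xywh_to_xyxy(b):
    cx, cy, w, h = b
    return np.array([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2])


def _iou_xyxy(a, b) -> float:
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / ua if ua > 0 else 0.0


def _norm_gts(gts_img):
    """Ground truths per image as [(class_id, (cx,cy,w,h)), ...]."""
    out = []
    for g in gts_img:
        c, box = g
        out.append((int(c), np.asarray(box, dtype=float)))
    return out


def match_detections(dets, gts, iou_thr: float):
    """Match detections to ground truths over an image set.

    ``dets``: per-image lists of Detection (box, score, class_id);
    ``gts``: per-image lists of (class_id, (cx, cy, w, h)). Matching is
    greedy per image in descending score; each gt is used at most once and
    a match needs IoU >= ``iou_thr`` and equal class. Returns a dict
    class_id -> :class:`PRData`.
    """
    if len(dets) != len(gts):
        raise ValueError("detections and ground truths cover different image counts")
    per_class: dict[int, list] = {}
    gt_counts: dict[int, int] = {}
    for img_dets, img_gts in zip(dets, gts):
        img_gts = _norm_gts(img_gts)
        for c, _ in img_gts:
            gt_counts[c] = gt_counts.get(c, 0) + 1
        used = [False] * len(img_gts)
        for d in sorted(img_dets, key=lambda d: -d.score):
            best_iou, best_j = 0.0, -1
            db = _xywh_to_xyxy(d.box)
            for j, (gc, gb) in enumerate(img_gts):
                if used[j] or gc != d.class_id:
                    continue
                i = _iou_xyxy(db, _xywh_to_xyxy(gb))
                if i >= iou_thr and i > best_iou:
                    best_iou, best_j = i, j
            tp = best_j >= 0
            if tp:
                used[best_j] = True
            per_class.setdefault(d.class_id, []).append((d.score, tp))
    out = {}
    for c in set(per_class) | set(gt_counts):
        recs = sorted(per_class.get(c, []), key=lambda r: -r[0])
        scores = np.array([r[0] for r in recs], dtype=float)
        is_tp = np.array([r[1] for r in recs], dtype=bool)
        out[c] = PRData(scores=scores, is_tp=is_tp, n_gt=gt_counts.get(c, 0))
    return out


def _pr_curve(pr: PRData):
    tp = np.cumsum(pr.is_tp)
    fp = np.cumsum(~pr.is_tp)
    recall = tp / pr.n_gt
    precision = tp / np.maximum(tp + fp, 1e-12)
    return recall, precision


def average_precision(pr: PRData) -> float:
    """101-point interpolated AP (COCO convention)."""
    if pr.n_gt == 0:
        warnings.warn("AP undefined for a class with no ground truths", stacklevel=2)
        return float("nan")
    if pr.scores.size == 0:
        return 0.0
    recall, precision = _pr_curve(pr)
    # precision envelope (best precision at recall >= r)
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    grid = np.linspace(0, 1, 101)
    idx = np.searchsorted(recall, grid, side="left")
    vals = np.where(idx < recall.size, prec_env[np.minimum(idx, recall.size - 1)], 0.0)
    return float(vals.mean())


def ap_all_point(pr: PRData) -> float:
    """Exact area under the interpolated PR curve (all-point variant)."""
    if pr.n_gt == 0 or pr.scores.size == 0:
        return 0.0 if pr.n_gt else float("nan")
    recall, precision = _pr_curve(pr)
    r = np.concatenate([[0.0], recall])
    p = np.concatenate([[1.0], precision])
    penv = np.maximum.accumulate(p[::-1])[::-1]
    return float(np.sum(np.diff(r) * penv[1:]))


def map_metrics(dets, gts, conf_mode: str = "max_f1"):
    """(mAP@0.5, mAP@0.5:0.95, precision, recall).

    mAP@0.5:0.95 averages AP over IoU thresholds 0.50, 0.55, ..., 0.95.
    P and R are reported at the confidence that maximizes F1 at IoU 0.5
    (``conf_mode='max_f1'``) or at a fixed threshold given as a float.
    """
    if all(len(g) == 0 for g in gts):
        raise ValueError("no ground truths in the evaluation set")
    thrs = np.arange(0.50, 0.96, 0.05)
    ap_per_thr = []
    matched50 = None
    for t in thrs:
        per_class = match_detections(dets, gts, float(t))
        aps = [average_precision(pr) for pr in per_class.values() if pr.n_gt > 0]
        ap_per_thr.append(float(np.mean(aps)) if aps else 0.0)
        if abs(t - 0.5) < 1e-9:
            matched50 = per_class
    map50 = ap_per_thr[0]
    map5095 = float(np.mean(ap_per_thr))

    scores = np.concatenate([pr.scores for pr in matched50.values()]) \
        if matched50 else np.zeros(0)
    tps = np.concatenate([pr.is_tp for pr in matched50.values()]) \
        if matched50 else np.zeros(0, bool)
    n_gt = sum(pr.n_gt for pr in matched50.values())
    order = np.argsort(-scores)
    scores, tps = scores[order], tps[order]
    if scores.size == 0:
        return map50, map5095, 0.0, 0.0
    tp_c = np.cumsum(tps)
    fp_c = np.cumsum(~tps)
    prec = tp_c / np.maximum(tp_c + fp_c, 1e-12)
    rec = tp_c / max(n_gt, 1)
    if conf_mode == "max_f1":
        f1 = 2 * prec * rec / np.maximum(prec + rec, 1e-12)
        i = int(np.argmax(f1))
    else:
        thr = float(conf_mode)
        above = np.where(scores >= thr)[0]
        i = int(above[-1]) if above.size else 0
    return map50, map5095, float(prec[i]), float(rec[i])


def confusion_matrix(dets, gts, conf_thr: float, iou_thr: float,
                     num_classes: int | None = None) -> np.ndarray:
    """(nc+1) x (nc+1) matrix: rows = predicted class (last row background,
    i.e. missed gts), columns = true class (last column background, i.e.
    false positives)."""
    if num_classes is None:
        cls_ids = [d.class_id for img in dets for d in img] + \
                  [int(c) for img in gts for (c, _) in img]
        num_classes = (max(cls_ids) + 1) if cls_ids else 1
    m = np.zeros((num_classes + 1, num_classes + 1), dtype=int)
    for img_dets, img_gts in zip(dets, gts):
        img_gts = _norm_gts(img_gts)
        used = [False] * len(img_gts)
        for d in sorted(img_dets, key=lambda d: -d.score):
            if d.score < conf_thr:
                continue
            best_iou, best_j = 0.0, -1
            db = _xywh_to_xyxy(d.box)
            for j, (gc, gb) in enumerate(img_gts):
                if used[j]:
                    continue
                i = _iou_xyxy(db, _xywh_to_xyxy(gb))
                if i >= iou_thr and i > best_iou:
                    best_iou, best_j = i, j
            if best_j >= 0:
                used[best_j] = True
                m[d.class_id, img_gts[best_j][0]] += 1
            else:
                m[d.class_id, num_classes] += 1        # FP vs background
        for j, (gc, _) in enumerate(img_gts):
            if not used[j]:
                m[num_classes, gc] += 1                # FN into background row
    return m


# ---------------------------------------------------------------------------
# complexity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplexityReport:
    n_params: int
    gflops: float
    input_size: int
    note: str = ("params = learnable scalars; GFLOPs = 2 x multiply-accumulates of "
                 "conv/linear layers at the stated square RGB input (normalization, "
                 "activations and pooling excluded)")


def count_params(model) -> int:
    """Exact count of learnable scalars."""
    return model.num_params()


def count_flops(model, input_size: int) -> float:
    """GFLOPs of one forward pass at ``input_size`` (2 FLOPs per MAC)."""
    if input_size % 32 != 0:
        raise ValueError("input_size must be a multiple of 32")
    was_training = model.training
    model.eval()
    x = np.zeros((1, 3, input_size, input_size), dtype=np.float32)
    mac_counter.active = True
    mac_counter.reset()
    try:
        model(x)
    finally:
        mac_counter.active = False
    if was_training:
        model.train()
    return 2.0 * mac_counter.macs / 1e9


def complexity_report(model, input_size: int = 640) -> ComplexityReport:
    return ComplexityReport(n_params=count_params(model),
                            gflops=count_flops(model, input_size),
                            input_size=input_size)
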