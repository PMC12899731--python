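"""Synthetic feeding-tray scenes with YOLO-format labels.

Real residual-feed imagery from shrimp farms is not redistributable, so the
benchmark here is a seeded renderer that emulates the *statistics* of such
data rather than its photographic appearance: dense small ochre particles
(~85 % below the COCO small-object threshold), ~40 % elongated shapes,
center-biased placement over a dark tray-mesh background, mutual
adhesion/overlap, uneven illumination, turbidity blur, and unlabeled
distractors (air bubbles, reflective glints, feces-like debris, shrimp
silhouettes) that exert false-positive/occlusion pressure.

All geometry is sampled in 640-px reference units and scaled, so the label
statistics are invariant to ``image_size``. Generation is a pure function
of (params, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "SceneParams", "ImageSample", "DatasetStats", "easy_params",
    "generate_sample", "generate_dataset", "augment_complete",
    "augment_local", "dataset_stats",
]

SMALL_AREA_NORM = (32.0 / 640.0) ** 2     # COCO-small threshold, normalized
ELONGATED_ASPECT = 2.0


@dataclass(frozen=True)
class SceneParams:
    image_size: int = 640
    particle_count: tuple = (8, 32)            # uniform-int range per image
    small_fraction_target: float = 0.85
    elongated_fraction_target: float = 0.40
    size_small_range: tuple = (12.0, 30.0)     # sqrt of box area, px @640
    size_large_range: tuple = (34.0, 64.0)
    round_aspect_range: tuple = (1.0, 1.6)
    elong_aspect_range: tuple = (2.8, 5.5)
    orient_jitter_deg: float = 8.0             # elongated particles stay near-axis-aligned
    center_bias_sigma: float = 0.18            # fraction of image width
    adhesion_prob: float = 0.35
    illumination_gradient: float = 0.35
    turbidity_blur_sigma: float = 0.8          # px @640
    bubble_rate: float = 3.0                   # Poisson means per image
    glint_rate: float = 2.0
    debris_rate: float = 1.5
    occluder_rate: float = 0.3
    mesh_period: float = 26.0                  # px @640

    def __post_init__(self):
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        for f in ("small_fraction_target", "elongated_fraction_target",
                  "adhesion_prob", "occluder_rate"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0 and f != "occluder_rate":
                raise ValueError(f"{f} must lie in [0,1]")


def easy_params(image_size: int = 160) -> SceneParams:
    """Large, well-separated, clean particles — the desk-scale training set."""
    return SceneParams(
        image_size=image_size, particle_count=(3, 6),
        size_small_range=(48.0, 90.0), size_large_range=(48.0, 90.0),
        small_fraction_target=0.0, adhesion_prob=0.0,
        illumination_gradient=0.15, turbidity_blur_sigma=0.5,
        bubble_rate=0.0, glint_rate=0.0, debris_rate=0.0, occluder_rate=0.0,
        center_bias_sigma=0.26)


@dataclass
class ImageSample:
    """Rendered scene plus its normalized YOLO labels."""

    image: np.ndarray                      # H x W x 3 uint8
    labels: list                           # [(class_id, cx, cy, w, h), ...]

    def __post_init__(self):
        for lab in self.labels:
            _, cx, cy, w, h = lab
            if not (0 <= cx <= 1 and 0 <= cy <= 1 and 0 < w <= 1 and 0 < h <= 1):
                raise ValueError(f"label outside the unit box: {lab}")


@dataclass(frozen=True)
class DatasetStats:
    n_images: int
    n_targets: int
    fraction_small: float
    fraction_elongated: float
    spatial_hist: np.ndarray       # 8x8 normalized center histogram
    size_hist: np.ndarray          # sqrt-area histogram (640-equivalent px bins)
    size_bins: np.ndarray


# ---------------------------------------------------------------------------
# geometry sampling
# ---------------------------------------------------------------------------

def _sample_particle(p: SceneParams, rng) -> dict:
    """Ellipse geometry in normalized units; bbox follows the rotated extents."""
    if rng.random() < p.small_fraction_target:
        s = rng.uniform(*p.size_small_range)
    else:
        s = rng.uniform(*p.size_large_range)
    if rng.random() < p.elongated_fraction_target:
        aspect = rng.uniform(*p.elong_aspect_range)
        axis = rng.choice([0.0, np.pi / 2])
        theta = axis + np.deg2rad(rng.uniform(-p.orient_jitter_deg, p.orient_jitter_deg))
    else:
        aspect = rng.uniform(*p.round_aspect_range)
        theta = rng.uniform(0, np.pi)
    a = s * np.sqrt(aspect) / 2.0 / 640.0       # semi-major, normalized
    b = s / np.sqrt(aspect) / 2.0 / 640.0
    ct, st = np.cos(theta), np.sin(theta)
    hx = np.sqrt((a * ct) ** 2 + (b * st) ** 2)
    hy = np.sqrt((a * st) ** 2 + (b * ct) ** 2)
    return {"a": a, "b": b, "theta": theta, "hx": hx, "hy": hy}


def _label_iou(b1, b2) -> float:
    x1, y1, w1, h1 = b1
    x2, y2, w2, h2 = b2
    ix = max(0.0, min(x1 + w1 / 2, x2 + w2 / 2) - max(x1 - w1 / 2, x2 - w2 / 2))
    iy = max(0.0, min(y1 + h1 / 2, y2 + h2 / 2) - max(y1 - h1 / 2, y2 - h2 / 2))
    inter = ix * iy
    return inter / (w1 * h1 + w2 * h2 - inter)


def _place_particles(p: SceneParams, rng):
    count = int(rng.integers(p.particle_count[0], p.particle_count[1] + 1))
    placed = []
    for _ in range(count):
        geom = _sample_particle(p, rng)
        for _try in range(60):
            if placed and rng.random() < p.adhesion_prob:
                host = placed[int(rng.integers(len(placed)))]
                ang = rng.uniform(0, 2 * np.pi)
                dist = (host["hx"] + geom["hx"]) * rng.uniform(0.55, 0.95)
                cx = host["cx"] + dist * np.cos(ang)
                cy = host["cy"] + dist * np.sin(ang)
            else:
                cx = rng.normal(0.5, p.center_bias_sigma)
                cy = rng.normal(0.5, p.center_bias_sigma)
            box = (cx, cy, 2 * geom["hx"], 2 * geom["hy"])
            if not (geom["hx"] < cx < 1 - geom["hx"] and geom["hy"] < cy < 1 - geom["hy"]):
                continue
            if p.adhesion_prob == 0.0 and any(
                    _label_iou(box, (q["cx"], q["cy"], 2 * q["hx"], 2 * q["hy"])) > 0
                    for q in placed):
                continue
            placed.append({**geom, "cx": cx, "cy": cy})
            break
    return placed


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _background(p: SceneParams, rng) -> np.ndarray:
    s = p.image_size
    base = np.array([62.0, 66.0, 56.0])
    img = np.tile(base, (s, s, 1))
    # low-frequency mottling (sediment / water tint)
    coarse = rng.normal(0, 9.0, size=(8, 8, 3))
    img += ndimage.zoom(coarse, (s / 8, s / 8, 1), order=1)
    # tray mesh: periodic brighter weave lines
    period = max(4.0, p.mesh_period * s / 640.0)
    xx, yy = np.meshgrid(np.arange(s), np.arange(s))
    lines = ((np.sin(2 * np.pi * xx / period) ** 2 > 0.90)
             | (np.sin(2 * np.pi * yy / period) ** 2 > 0.90))
    img[lines] += 22.0
    img += rng.normal(0, 3.0, size=img.shape)
    return img


def _paint_ellipse(img, idmap, pid, cx, cy, a, b, theta, color, rng, alpha=1.0,
                   shade=0.25):
    s = img.shape[0]
    hx = np.sqrt((a * np.cos(theta)) ** 2 + (b * np.sin(theta)) ** 2)
    hy = np.sqrt((a * np.sin(theta)) ** 2 + (b * np.cos(theta)) ** 2)
    x0 = max(0, int((cx - hx) * s) - 1)
    x1 = min(s, int((cx + hx) * s) + 2)
    y0 = max(0, int((cy - hy) * s) - 1)
    y1 = min(s, int((cy + hy) * s) + 2)
    if x1 <= x0 or y1 <= y0:
        return
    xs = (np.arange(x0, x1) + 0.5) / s - cx
    ys = (np.arange(y0, y1) + 0.5) / s - cy
    u = np.cos(theta) * xs[None, :] + np.sin(theta) * ys[:, None]
    v = -np.sin(theta) * xs[None, :] + np.cos(theta) * ys[:, None]
    q = (u / a) ** 2 + (v / b) ** 2
    soft = np.clip((1.0 - q) * 4.0, 0.0, 1.0) * alpha
    inside = soft > 0
    if not inside.any():
        return
    shading = 1.0 + shade * (-u / a)
    patch = img[y0:y1, x0:x1]
    col = color[None, None, :] * shading[..., None]
    col = col + rng.normal(0, 4.0, size=col.shape)
    patch[:] = patch * (1 - soft[..., None]) + col * soft[..., None]
    if idmap is not None:
        idmap[y0:y1, x0:x1][soft > 0.5] = pid


def generate_sample(p: SceneParams, rng) -> ImageSample:
    """Render one scene; labels cover every particle that stays visible.

    Distractors and occluders are never labeled; a particle whose visible
    area drops below 25 % (occluded by a silhouette or buried by a later
    particle) loses its label.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    s = p.image_size
    img = _background(p, rng)
    idmap = np.full((s, s), -1, dtype=np.int32)

    # feces-like debris (unlabeled, visually similar to feed)
    for _ in range(rng.poisson(p.debris_rate)):
        _paint_ellipse(img, None, 0, rng.uniform(0.1, 0.9), rng.uniform(0.1, 0.9),
                       rng.uniform(6, 14) / 640, rng.uniform(3, 7) / 640,
                       rng.uniform(0, np.pi), np.array([72.0, 54.0, 38.0]), rng)

    particles = _place_particles(p, rng)
    base_col = np.array([150.0, 112.0, 58.0])
    for pid, q in enumerate(particles):
        col = base_col + rng.normal(0, 14.0, size=3)
        _paint_ellipse(img, idmap, pid, q["cx"], q["cy"], q["a"], q["b"], q["theta"],
                       col, rng)
    full_counts = np.bincount(idmap[idmap >= 0], minlength=max(len(particles), 1))

    # shrimp-silhouette occluders over the particles
    for _ in range(rng.poisson(p.occluder_rate)):
        _paint_ellipse(img, idmap, -2, rng.uniform(0.2, 0.8), rng.uniform(0.2, 0.8),
                       rng.uniform(45, 90) / 640, rng.uniform(14, 26) / 640,
                       rng.uniform(0, np.pi), np.array([84.0, 88.0, 92.0]), rng,
                       alpha=0.85, shade=0.1)

    # bubbles and glints on top
    for _ in range(rng.poisson(p.bubble_rate)):
        _paint_ellipse(img, None, 0, rng.uniform(0.05, 0.95), rng.uniform(0.05, 0.95),
                       rng.uniform(2.5, 6) / 640, rng.uniform(2.5, 6) / 640, 0.0,
                       np.array([195.0, 205.0, 212.0]), rng, alpha=0.4, shade=0.0)
    for _ in range(rng.poisson(p.glint_rate)):
        _paint_ellipse(img, None, 0, rng.uniform(0.05, 0.95), rng.uniform(0.05, 0.95),
                       rng.uniform(1.2, 2.5) / 640, rng.uniform(1.2, 2.5) / 640, 0.0,
                       np.array([238.0, 240.0, 238.0]), rng, alpha=0.9, shade=0.0)

    # uneven illumination: multiplicative linear gradient in a random direction
    if p.illumination_gradient > 0:
        ang = rng.uniform(0, 2 * np.pi)
        xx, yy = np.meshgrid(np.linspace(-.5, .5, s), np.linspace(-.5, .5, s))
        proj = xx * np.cos(ang) + yy * np.sin(ang)
        img *= (1.0 + 2 * p.illumination_gradient * proj)[..., None]

    sigma = p.turbidity_blur_sigma * s / 640.0
    if sigma > 0.05:
        img = ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0))
    img += rng.normal(0, 2.5, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    visible = np.bincount(idmap[idmap >= 0], minlength=max(len(particles), 1))
    labels = []
    for pid, q in enumerate(particles):
        if full_counts[pid] == 0:
            continue
        if visible[pid] / full_counts[pid] < 0.25:
            continue
        labels.append((0, float(q["cx"]), float(q["cy"]),
                       float(2 * q["hx"]), float(2 * q["hy"])))
    return ImageSample(image=img, labels=labels)


# ---------------------------------------------------------------------------
# dataset writing
# ---------------------------------------------------------------------------

def generate_dataset(p: SceneParams, n: int, split_ratio: float, out_dir,
                     seed: int = 0, force: bool = False, class_names=("feed",)):
    """Render ``n`` scenes into a YOLO directory layout with a seeded split.

    ``round(n * split_ratio)`` images go to train, the rest to val. Returns
    (train_stems, val_stems). Refuses to write into a non-empty directory
    unless ``force`` is set.
    """
    if n < 2:
        raise ValueError("need at least 2 images to split")
    if not 0 < split_ratio < 1:
        raise ValueError("split_ratio must lie strictly between 0 and 1")
    from PIL import Image
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty; pass force=True to overwrite")
    for sub in ("images/train", "images/val", "labels/train", "labels/val"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n + 1)
    split_rng = np.random.default_rng(child_seeds[-1])
    order = split_rng.permutation(n)
    n_train = int(round(n * split_ratio))
    train_ids = set(order[:n_train].tolist())

    train_stems, val_stems = [], []
    for i in range(n):
        sample = generate_sample(p, np.random.default_rng(child_seeds[i]))
        split = "train" if i in train_ids else "val"
        stem = f"scene_{i:05d}"
        Image.fromarray(sample.image).save(out / "images" / split / f"{stem}.png")
        with open(out / "labels" / split / f"{stem}.txt", "w") as fh:
            for c, cx, cy, w, h in sample.labels:
                fh.write(f"{int(c)} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}\n")
        (train_stems if split == "train" else val_stems).append(stem)

    yaml_text = (f"path: {out.resolve()}\ntrain: images/train\nval: images/val\n"
                 f"nc: {len(class_names)}\nnames: {list(class_names)}\n")
    (out / "data.yaml").write_text(yaml_text)
    return train_stems, val_stems


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _rot90_labels(labels, k):
    out = labels
    for _ in range(k % 4):
        out = [(c, cy, 1.0 - cx, h, w) for (c, cx, cy, w, h) in out]
    return out


def augment_complete(s: ImageSample, rng, *, crop=None, rot_k=None, flip=None,
                     brightness=None, contrast=None,
                     crop_scale=(0.6, 1.0), keep_area=0.30) -> ImageSample:
    """Full augmentation: random crop, right-angle rotation, horizontal flip
    and brightness/contrast jitter, all label-consistent.

    A crop keeps a box only if at least ``keep_area`` of its area survives.
    Rotation is restricted to multiples of 90 deg so box geometry stays
    exact without particle masks. Explicit keyword values override the
    random draws (identity values reproduce the input bit-for-bit).
    """
    from PIL import Image
    img = s.image
    labels = list(s.labels)
    h, w = img.shape[:2]

    if crop is None:
        sc = rng.uniform(*crop_scale)
        cw, ch = int(round(w * sc)), int(round(h * sc))
        x0 = int(rng.integers(0, w - cw + 1))
        y0 = int(rng.integers(0, h - ch + 1))
        crop = (x0, y0, cw, ch)
    x0, y0, cw, ch = crop
    if (x0, y0, cw, ch) != (0, 0, w, h):
        img = img[y0:y0 + ch, x0:x0 + cw]
        new_labels = []
        for c, cx, cy, bw, bh in labels:
            bx1, by1 = cx * w - bw * w / 2, cy * h - bh * h / 2
            bx2, by2 = cx * w + bw * w / 2, cy * h + bh * h / 2
            ix1, iy1 = max(bx1, x0), max(by1, y0)
            ix2, iy2 = min(bx2, x0 + cw), min(by2, y0 + ch)
            if ix2 <= ix1 or iy2 <= iy1:
                continue
            if (ix2 - ix1) * (iy2 - iy1) < keep_area * (bx2 - bx1) * (by2 - by1):
                continue
            new_labels.append((c, ((ix1 + ix2) / 2 - x0) / cw, ((iy1 + iy2) / 2 - y0) / ch,
                               (ix2 - ix1) / cw, (iy2 - iy1) / ch))
        labels = new_labels
        img = np.asarray(Image.fromarray(img).resize((w, h), Image.BILINEAR))

    if rot_k is None:
        rot_k = int(rng.integers(0, 4))
    if rot_k % 4:
        img = np.ascontiguousarray(np.rot90(img, rot_k))
        labels = _rot90_labels(labels, rot_k)

    if flip is None:
        flip = rng.random() < 0.5
    if flip:
        img = np.ascontiguousarray(img[:, ::-1])
        labels = [(c, 1.0 - cx, cy, bw, bh) for (c, cx, cy, bw, bh) in labels]

    if brightness is None:
        brightness = rng.uniform(0.8, 1.2)
    if contrast is None:
        contrast = rng.uniform(0.8, 1.2)
    if brightness != 1.0 or contrast != 1.0:
        x = img.astype(np.float32)
        x = (x - 128.0) * contrast + 128.0
        x = x * brightness
        img = np.clip(x, 0, 255).astype(np.uint8)

    return ImageSample(image=img, labels=labels)


def augment_local(s: ImageSample, donors, rng, paste_count=None, max_tries=40,
                  iou_cap=0.10) -> ImageSample:
    """Targeted small-object augmentation: crop labeled particles from donor
    scenes and paste them at center-biased free locations with feathered
    blending; pasted labels are appended. Returns the sample unchanged
    (with a warning) if no free spot is found."""
    if not donors:
        raise ValueError("donor pool is empty")
    donor_labels = [(d, lab) for d in donors for lab in d.labels]
    if paste_count is None:
        paste_count = int(rng.integers(1, 5))
    if paste_count == 0 or not donor_labels:
        return ImageSample(image=s.image.copy(), labels=list(s.labels))
    img = s.image.astype(np.float32)
    h, w = img.shape[:2]
    labels = list(s.labels)
    pasted = 0
    for _ in range(paste_count):
        donor, (c, cx, cy, bw, bh) = donor_labels[int(rng.integers(len(donor_labels)))]
        dh, dw = donor.image.shape[:2]
        px0 = int(np.floor((cx - bw / 2) * dw))
        py0 = int(np.floor((cy - bh / 2) * dh))
        px1 = int(np.ceil((cx + bw / 2) * dw))
        py1 = int(np.ceil((cy + bh / 2) * dh))
        patch = donor.image[max(py0, 0):py1, max(px0, 0):px1].astype(np.float32)
        ph, pw = patch.shape[:2]
        if ph < 2 or pw < 2:
            continue
        ok = False
        for _t in range(max_tries):
            ncx = float(np.clip(rng.normal(0.5, 0.18), pw / w / 2, 1 - pw / w / 2))
            ncy = float(np.clip(rng.normal(0.5, 0.18), ph / h / 2, 1 - ph / h / 2))
            cand = (ncx, ncy, pw / w, ph / h)
            if all(_label_iou(cand, (lx, ly, lw, lh)) <= iou_cap
                   for (_, lx, ly, lw, lh) in labels):
                ok = True
                break
        if not ok:
            warnings.warn("augment_local: no free paste location found", stacklevel=2)
            continue
        x0 = int(round(ncx * w - pw / 2))
        y0 = int(round(ncy * h - ph / 2))
        alpha = np.ones((ph, pw), dtype=np.float32)
        alpha[0, :] = alpha[-1, :] = alpha[:, 0] = alpha[:, -1] = 0.0
        alpha = ndimage.gaussian_filter(alpha, 1.0)[..., None]
        img[y0:y0 + ph, x0:x0 + pw] = (img[y0:y0 + ph, x0:x0 + pw] * (1 - alpha)
                                       + patch * alpha)
        labels.append((c, x0 / w + pw / w / 2, y0 / h + ph / h / 2, pw / w, ph / h))
        pasted += 1
    return ImageSample(image=np.clip(img, 0, 255).astype(np.uint8), labels=labels)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def dataset_stats(samples) -> DatasetStats:
    """Label-derived statistics of a sample collection.

    "Small" means normalized box area below (32/640)^2 — the COCO small
    threshold at the 640-px reference scale; "elongated" means bounding-box
    aspect ratio above 2.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("no samples")
    labs = []
    for s in samples:
        labels = s.labels if hasattr(s, "labels") else s
        labs.extend(labels)
    n_targets = len(labs)
    if n_targets == 0:
        return DatasetStats(len(samples), 0, 0.0, 0.0,
                            np.zeros((8, 8)), np.zeros(8), np.zeros(9))
    arr = np.asarray([(cx, cy, w, h) for (_, cx, cy, w, h) in labs], dtype=float)
    area = arr[:, 2] * arr[:, 3]
    aspect = np.maximum(arr[:, 2], arr[:, 3]) / np.minimum(arr[:, 2], arr[:, 3])
    frac_small = float((area < SMALL_AREA_NORM).mean())
    frac_elong = float((aspect > ELONGATED_ASPECT).mean())
    spatial, _, _ = np.histogram2d(arr[:, 1], arr[:, 0], bins=8, range=[[0, 1], [0, 1]])
    spatial = spatial / spatial.sum()
    size_bins = np.array([0, 8, 16, 24, 32, 48, 64, 96, 640], dtype=float)
    size_hist, _ = np.histogram(np.sqrt(area) * 640.0, bins=size_bins)
    return DatasetStats(len(samples), n_targets, frac_small, frac_elong,
                        spatial, size_hist / n_targets, size_bins)
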