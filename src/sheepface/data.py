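"""Dataset handling: YOLO-format label IO, the 8-1-1 stratified split,
augmentations, letterboxing, mosaic stitching, anchor estimation and the
synthetic sheep-face fixture generator.

Labels follow the de-facto YOLO text dialect: one object per line,
``class cx cy w h`` with coordinates normalised to [0, 1] and 0-based
class ids.

The fixture generator draws procedural sheep faces (elliptical head, ear
triangles, eyes, muzzle) whose identity-specific dark spot patterns around
the eyes, ears and mouth emulate the natural markings that make individual
sheep visually separable.  It exists so the full train/eval pipeline runs
without any external dataset; see docs/methods.md for what it does and
does not emulate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image, ImageDraw

log = logging.getLogger(__name__)

__all__ = [
    "LabeledImage", "DatasetIndex", "read_labels", "write_labels",
    "load_dataset", "save_dataset", "split_dataset",
    "augment_brightness", "augment_rotate45", "augment_vflip",
    "letterbox", "apply_letterbox_to_box", "invert_letterbox_on_box",
    "mosaic4", "kmeans_anchors", "generate_fixture_dataset",
]

GRAY_FILL = 114  # pad/fill value used by letterboxing and rotation


@dataclass
class LabeledImage:
    """An image plus its ground-truth boxes in normalised YOLO coordinates."""

    image: np.ndarray | None
    boxes: list[tuple[int, float, float, float, float]]
    path: Path | None = None

    def __post_init__(self):
        for cid, cx, cy, w, h in self.boxes:
            if w <= 0 or h <= 0:
                raise ValueError(f"non-positive box size ({w}, {h})")
            if not (-1e-6 <= cx - w / 2 and cx + w / 2 <= 1 + 1e-6
                    and -1e-6 <= cy - h / 2 and cy + h / 2 <= 1 + 1e-6):
                raise ValueError(f"box ({cx},{cy},{w},{h}) outside [0,1]^2")
            if cid < 0:
                raise ValueError("negative class id")

    def load(self) -> np.ndarray:
        if self.image is None:
            self.image = np.asarray(Image.open(self.path).convert("RGB"))
        return self.image


@dataclass
class DatasetIndex:
    """Disjoint train/val/test splits over a pool of labelled images."""

    train: list[LabeledImage]
    val: list[LabeledImage]
    test: list[LabeledImage]
    nc: int
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        ids = [id(x) for part in (self.train, self.val, self.test) for x in part]
        if len(ids) != len(set(ids)):
            raise ValueError("splits are not disjoint")
        if not self.class_names:
            self.class_names = [f"class_{i}" for i in range(self.nc)]

    @property
    def items(self) -> list[LabeledImage]:
        return self.train + self.val + self.test


# ---------------------------------------------------------------- label IO --

def read_labels(path) -> list[tuple[int, float, float, float, float]]:
    boxes = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        cid, cx, cy, w, h = int(parts[0]), *map(float, parts[1:5])
        boxes.append((cid, cx, cy, w, h))
    return boxes


def write_labels(path, boxes) -> None:
    lines = [f"{cid} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}"
             for cid, cx, cy, w, h in boxes]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def save_dataset(items: list[LabeledImage], out_dir, nc: int,
                 class_names=None) -> Path:
    """Write images/ + labels/ + dataset.yaml; returns the yaml path."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    for i, item in enumerate(items):
        name = f"img_{i:05d}"
        img_path = out / "images" / f"{name}.png"
        Image.fromarray(item.load()).save(img_path)
        write_labels(out / "labels" / f"{name}.txt", item.boxes)
        item.path = img_path
    meta = {"path": str(out), "nc": nc,
            "names": list(class_names or [f"class_{i}" for i in range(nc)])}
    ypath = out / "dataset.yaml"
    ypath.write_text(yaml.safe_dump(meta, sort_keys=False))
    return ypath


def load_dataset(root) -> tuple[list[LabeledImage], int, list[str]]:
    """Load an images/ + labels/ directory tree described by dataset.yaml."""
    root = Path(root)
    meta = yaml.safe_load((root / "dataset.yaml").read_text())
    items = []
    for img_path in sorted((root / "images").iterdir()):
        lbl = root / "labels" / (img_path.stem + ".txt")
        items.append(LabeledImage(None, read_labels(lbl), path=img_path))
    return items, int(meta["nc"]), list(meta["names"])


# -------------------------------------------------------------------- split --

def split_dataset(items: list[LabeledImage], seed: int,
                  ratios=(0.8, 0.1, 0.1), nc: int | None = None,
                  class_names=None) -> DatasetIndex:
    """Deterministic stratified 8-1-1 split.

    Global sizes: |val| = |test| = floor(0.1 * n); train takes the
    remainder (12,410 items -> 9,928/1,241/1,241).  Stratification keeps
    every identity represented in the training split; val/test quotas per
    class are apportioned by largest remainder so the global counts are
    exact.
    """
    n = len(items)
    if n < 10:
        raise ValueError("need at least 10 items to split 8-1-1")
    rng = np.random.default_rng(seed)
    n_val = int(ratios[1] * n)
    n_test = int(ratios[2] * n)

    def primary_class(it: LabeledImage) -> int:
        return it.boxes[0][0] if it.boxes else -1

    classes = sorted({primary_class(it) for it in items})
    if nc is not None and len(classes) < nc:
        log.warning("only %d of %d classes present in the item pool",
                    len(classes), nc)
    by_class = {c: [i for i, it in enumerate(items) if primary_class(it) == c]
                for c in classes}
    for idxs in by_class.values():
        rng.shuffle(idxs)

    def apportion(total: int) -> dict[int, int]:
        quota = {c: ratios[1] * len(by_class[c]) for c in classes}
        base = {c: int(quota[c]) for c in classes}
        # never exhaust a class: leave at least one item for train
        for c in classes:
            base[c] = min(base[c], max(len(by_class[c]) - 1, 0))
        short = total - sum(base.values())
        order = sorted(classes, key=lambda c: (-(quota[c] - base[c]), c))
        for c in order:
            if short <= 0:
                break
            if base[c] + 1 < len(by_class[c]):
                base[c] += 1
                short -= 1
        return base

    val_q = apportion(n_val)
    val_idx, test_idx = [], []
    for c in classes:
        pool = by_class[c]
        val_idx += pool[:val_q[c]]
    remaining = {c: by_class[c][val_q[c]:] for c in classes}
    test_q = {}
    quota = {c: ratios[2] * len(by_class[c]) for c in classes}
    base = {c: min(int(quota[c]), max(len(remaining[c]) - 1, 0)) for c in classes}
    short = n_test - sum(base.values())
    for c in sorted(classes, key=lambda c: (-(quota[c] - base[c]), c)):
        if short <= 0:
            break
        if base[c] + 1 < len(remaining[c]):
            base[c] += 1
            short -= 1
    for c in classes:
        test_idx += remaining[c][:base[c]]
    chosen = set(val_idx) | set(test_idx)
    train_idx = [i for i in range(n) if i not in chosen]
    return DatasetIndex([items[i] for i in train_idx],
                        [items[i] for i in val_idx],
                        [items[i] for i in test_idx],
                        nc=nc if nc is not None else (max(classes) + 1),
                        class_names=class_names or [])


# ------------------------------------------------------------- augmentation --

def augment_brightness(item: LabeledImage, factor: float) -> LabeledImage:
    """Scale pixel intensities by ``factor`` and clip to [0, 255]."""
    img = item.load().astype(np.float32) * factor
    return LabeledImage(np.clip(img, 0, 255).astype(np.uint8), list(item.boxes))


def augment_vflip(item: LabeledImage) -> LabeledImage:
    """Flip top-bottom; box centers reflect as cy -> 1 - cy."""
    img = item.load()[::-1].copy()
    boxes = [(cid, cx, 1.0 - cy, w, h) for cid, cx, cy, w, h in item.boxes]
    return LabeledImage(img, boxes)


def augment_rotate45(item: LabeledImage, angle: float = 45.0) -> LabeledImage:
    """Rotate the image about its center; boxes become the axis-aligned
    envelopes of their rotated corners, clipped to the frame.

    Boxes rotated fully out of frame (or collapsed by clipping) are
    dropped with a logged count.
    """
    img = item.load()
    h, w = img.shape[:2]
    pil = Image.fromarray(img).rotate(angle, resample=Image.BILINEAR,
                                      fillcolor=(GRAY_FILL,) * 3)
    out = np.asarray(pil)
    # PIL rotates the content counterclockwise by `angle` about the center;
    # in array coordinates (y down) a content point rotates with the
    # matrix [[cos, sin], [-sin, cos]].
    t = math.radians(angle)
    cos_t, sin_t = math.cos(t), math.sin(t)
    cx0, cy0 = w / 2.0, h / 2.0
    boxes, dropped = [], 0
    for cid, cx, cy, bw, bh in item.boxes:
        px, py, pw_, ph_ = cx * w, cy * h, bw * w, bh * h
        corners = np.array([[px - pw_ / 2, py - ph_ / 2], [px + pw_ / 2, py - ph_ / 2],
                            [px - pw_ / 2, py + ph_ / 2], [px + pw_ / 2, py + ph_ / 2]])
        rel = corners - (cx0, cy0)
        rot = rel @ np.array([[cos_t, -sin_t], [sin_t, cos_t]]) + (cx0, cy0)
        x1, y1 = rot.min(axis=0)
        x2, y2 = rot.max(axis=0)
        x1, x2 = np.clip([x1, x2], 0, w)
        y1, y2 = np.clip([y1, y2], 0, h)
        if x2 - x1 < 2 or y2 - y1 < 2:
            dropped += 1
            continue
        boxes.append((cid, (x1 + x2) / 2 / w, (y1 + y2) / 2 / h,
                      (x2 - x1) / w, (y2 - y1) / h))
    if dropped:
        log.info("rotate45: dropped %d box(es) leaving the frame", dropped)
    return LabeledImage(out, boxes)


# ---------------------------------------------------------------- letterbox --

def letterbox(img: np.ndarray, target: int):
    """Isotropic resize + symmetric gray padding to ``target x target``.

    Returns (canvas, scale, (pad_x, pad_y)); the transform maps a source
    pixel coordinate p to p * scale + pad.
    """
    if target % 32:
        raise ValueError("letterbox target must be divisible by 32")
    h, w = img.shape[:2]
    scale = min(target / h, target / w)
    nw, nh = max(1, round(w * scale)), max(1, round(h * scale))
    resized = np.asarray(Image.fromarray(img).resize((nw, nh), Image.BILINEAR))
    canvas = np.full((target, target, 3), GRAY_FILL, dtype=np.uint8)
    pad_x, pad_y = (target - nw) // 2, (target - nh) // 2
    canvas[pad_y:pad_y + nh, pad_x:pad_x + nw] = resized
    return canvas, scale, (pad_x, pad_y)


def apply_letterbox_to_box(box, scale, pad):
    x1, y1, x2, y2 = box
    return (x1 * scale + pad[0], y1 * scale + pad[1],
            x2 * scale + pad[0], y2 * scale + pad[1])


def invert_letterbox_on_box(box, scale, pad):
    x1, y1, x2, y2 = box
    return ((x1 - pad[0]) / scale, (y1 - pad[1]) / scale,
            (x2 - pad[0]) / scale, (y2 - pad[1]) / scale)


# ------------------------------------------------------------------- mosaic --

def mosaic4(items, seed: int | np.random.Generator, out_size: int = 640) -> LabeledImage:
    """Stitch four labelled images into a 2x2 canvas with remapped boxes."""
    if len(items) != 4:
        raise ValueError("mosaic4 needs exactly 4 items")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(4)
    half = out_size // 2
    canvas = np.full((out_size, out_size, 3), GRAY_FILL, dtype=np.uint8)
    boxes = []
    offsets = [(0, 0), (half, 0), (0, half), (half, half)]
    for quad, (ox, oy) in zip(order, offsets):
        item = items[int(quad)]
        tile, scale, pad = letterbox_any(item.load(), half)
        canvas[oy:oy + half, ox:ox + half] = tile
        ih, iw = item.load().shape[:2]
        for cid, cx, cy, w, h in item.boxes:
            x1, y1 = (cx - w / 2) * iw, (cy - h / 2) * ih
            x2, y2 = (cx + w / 2) * iw, (cy + h / 2) * ih
            x1, y1, x2, y2 = apply_letterbox_to_box((x1, y1, x2, y2), scale, pad)
            x1, x2 = np.clip([x1 + ox, x2 + ox], 0, out_size)
            y1, y2 = np.clip([y1 + oy, y2 + oy], 0, out_size)
            if x2 - x1 < 2 or y2 - y1 < 2:
                continue
            boxes.append((cid, (x1 + x2) / 2 / out_size, (y1 + y2) / 2 / out_size,
                          (x2 - x1) / out_size, (y2 - y1) / out_size))
    return LabeledImage(canvas, boxes)


def letterbox_any(img: np.ndarray, target: int):
    """Letterbox to an arbitrary (not necessarily /32) square size."""
    h, w = img.shape[:2]
    scale = min(target / h, target / w)
    nw, nh = max(1, round(w * scale)), max(1, round(h * scale))
    resized = np.asarray(Image.fromarray(img).resize((nw, nh), Image.BILINEAR))
    canvas = np.full((target, target, 3), GRAY_FILL, dtype=np.uint8)
    pad_x, pad_y = (target - nw) // 2, (target - nh) // 2
    canvas[pad_y:pad_y + nh, pad_x:pad_x + nw] = resized
    return canvas, scale, (pad_x, pad_y)


# ------------------------------------------------------------------ anchors --

def _wh_iou(wh1: np.ndarray, wh2: np.ndarray) -> np.ndarray:
    """IoU of (w, h) pairs as if corner-anchored at the origin."""
    inter = (np.minimum(wh1[:, None, 0], wh2[None, :, 0])
             * np.minimum(wh1[:, None, 1], wh2[None, :, 1]))
    union = (wh1[:, 0] * wh1[:, 1])[:, None] + (wh2[:, 0] * wh2[:, 1])[None, :] - inter
    return inter / union


def kmeans_anchors(boxes_wh, k: int = 9, generations: int = 200,
                   seed: int = 0) -> np.ndarray:
    """Anchor estimation: IoU-distance K-means followed by random mutation
    accepted whenever the mean best-anchor IoU over the boxes improves.

    Returns (k, 2) anchors sorted ascending by area (grouped 3 per scale
    by the caller).
    """
    wh = np.asarray(boxes_wh, dtype=np.float64).reshape(-1, 2)
    if len(wh) < k:
        raise ValueError(f"need at least {k} boxes, got {len(wh)}")
    rng = np.random.default_rng(seed)
    if np.allclose(wh, wh[0]):  # degenerate: single size
        anchors = np.tile(wh[0], (k, 1))
        return anchors[np.argsort(anchors.prod(axis=1), kind="stable")]
    anchors = wh[rng.choice(len(wh), size=k, replace=False)].copy()
    for _ in range(60):
        assign = _wh_iou(wh, anchors).argmax(axis=1)
        new = anchors.copy()
        for j in range(k):
            sel = wh[assign == j]
            if len(sel):
                new[j] = sel.mean(axis=0)
        if np.allclose(new, anchors):
            break
        anchors = new

    def fitness(a):
        return _wh_iou(wh, a).max(axis=1).mean()

    best, best_fit = anchors.copy(), fitness(anchors)
    for _ in range(generations):
        mut = best * np.clip(rng.normal(1.0, 0.1, size=best.shape), 0.5, 2.0)
        f = fitness(mut)
        if f > best_fit:
            best, best_fit = mut, f
    return best[np.argsort(best.prod(axis=1), kind="stable")]


# ------------------------------------------------------------------ fixture --

_SPOT_COLORS = [(40, 26, 13), (20, 20, 20), (74, 44, 18), (99, 60, 28),
                (52, 36, 26), (30, 18, 34)]
_COAT_BASE = np.array([225, 219, 204], dtype=float)

# face-local anchor points for identity spots (x, y in face units, y down):
# around the eyes, ears, cheeks and mouth
_SPOT_SITES = np.array([
    (-0.42, -0.18), (0.42, -0.18),   # around the eyes
    (-0.62, -0.72), (0.62, -0.72),   # ears
    (-0.50, 0.30), (0.50, 0.30),     # cheeks
    (-0.18, 0.66), (0.18, 0.66),     # mouth corners
    (0.0, 0.15),                     # nose bridge
])


def _class_style(class_id: int, seed: int) -> dict:
    rng = np.random.default_rng((seed, 1009 + class_id))
    n_spots = int(rng.integers(2, 6))
    sites = rng.choice(len(_SPOT_SITES), size=n_spots, replace=False)
    return {
        "spot_sites": _SPOT_SITES[sites] + rng.normal(0, 0.05, (n_spots, 2)),
        "spot_radii": rng.uniform(0.08, 0.2, n_spots),
        "spot_color": _SPOT_COLORS[int(rng.integers(len(_SPOT_COLORS)))],
        "coat_tint": rng.uniform(-18, 18, 3),
        "muzzle_dark": bool(rng.integers(2)),
        "ear_tips_dark": bool(rng.integers(2)),
    }


def _draw_face(size: int, style: dict, rng: np.random.Generator):
    """Draw one jittered face; returns (uint8 image, exact face box px)."""
    bg = tuple(int(v) for v in rng.uniform(60, 190, 3))
    img = Image.new("RGB", (size, size), bg)
    d = ImageDraw.Draw(img)
    # light background clutter
    for _ in range(int(rng.integers(2, 6))):
        x, y = rng.uniform(0, size, 2)
        r = rng.uniform(size * 0.02, size * 0.1)
        shade = tuple(int(np.clip(c + rng.uniform(-35, 35), 0, 255)) for c in bg)
        d.ellipse([x - r, y - r, x + r, y + r], fill=shade)

    fs = rng.uniform(0.24, 0.40) * size          # face half-width
    cx = rng.uniform(0.30, 0.70) * size
    cy = rng.uniform(0.32, 0.68) * size
    coat = tuple(int(np.clip(v, 0, 255))
                 for v in _COAT_BASE + style["coat_tint"] + rng.normal(0, 4, 3))

    def fx(p):  # face-local -> pixel
        return cx + p[0] * fs, cy + p[1] * fs

    # ears: triangles above the head ellipse
    ear_color = ((70, 52, 40) if style["ear_tips_dark"] else coat)
    for sx in (-1, 1):
        tip = fx((sx * 0.95, -1.35))
        base1 = fx((sx * 0.35, -0.75))
        base2 = fx((sx * 1.05, -0.55))
        d.polygon([tip, base1, base2], fill=ear_color, outline=(60, 50, 40))
    # head
    head_box = [cx - fs, cy - 1.1 * fs, cx + fs, cy + 1.1 * fs]
    d.ellipse(head_box, fill=coat, outline=(90, 80, 70))
    # identity spots
    for (sxy, r) in zip(style["spot_sites"], style["spot_radii"]):
        px, py = fx(sxy)
        rr = r * fs
        d.ellipse([px - rr, py - rr * 0.8, px + rr, py + rr * 0.8],
                  fill=style["spot_color"])
    # eyes
    for sx in (-1, 1):
        ex, ey = fx((sx * 0.42, -0.18))
        r = 0.09 * fs
        d.ellipse([ex - r, ey - r, ex + r, ey + r], fill=(25, 20, 18))
    # muzzle
    mz = (120, 96, 84) if style["muzzle_dark"] else (190, 170, 160)
    mx, my = fx((0.0, 0.62))
    d.ellipse([mx - 0.42 * fs, my - 0.30 * fs, mx + 0.42 * fs, my + 0.42 * fs],
              fill=mz, outline=(90, 75, 65))
    for sx in (-1, 1):
        nx, ny = fx((sx * 0.14, 0.58))
        d.ellipse([nx - 0.04 * fs, ny - 0.06 * fs, nx + 0.04 * fs, ny + 0.06 * fs],
                  fill=(30, 22, 20))

    # exact face extent: head ellipse union ear triangles
    x1 = min(head_box[0], fx((-1.05, 0))[0])
    x2 = max(head_box[2], fx((1.05, 0))[0])
    y1 = min(head_box[1], fx((0, -1.35))[1])
    y2 = head_box[3]
    arr = np.asarray(img, dtype=np.float32)
    arr *= rng.uniform(0.62, 1.32)                      # brightness jitter
    arr += rng.normal(0, 5, arr.shape)                  # sensor noise
    return np.clip(arr, 0, 255).astype(np.uint8), (x1, y1, x2, y2)


def generate_fixture_dataset(n_classes: int = 5, n_per_class: int = 20,
                             image_size: int = 320, seed: int = 7,
                             out_dir=None) -> DatasetIndex:
    """Generate a labelled synthetic sheep-face dataset and split it 8-1-1.

    Each identity class gets a seed-stable spot pattern (count, position
    and colour of dark blobs around eyes/ears/cheeks/mouth); each image
    jitters pose, scale, brightness and background.  Exact face boxes are
    emitted as YOLO labels.  With ``out_dir`` the images, labels and a
    dataset.yaml are also written to disk.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 identity classes")
    items = []
    for c in range(n_classes):
        style = _class_style(c, seed)
        for i in range(n_per_class):
            rng = np.random.default_rng((seed, c, i))
            img, (x1, y1, x2, y2) = _draw_face(image_size, style, rng)
            x1, x2 = np.clip([x1, x2], 0, image_size)
            y1, y2 = np.clip([y1, y2], 0, image_size)
            box = (c, (x1 + x2) / 2 / image_size, (y1 + y2) / 2 / image_size,
                   (x2 - x1) / image_size, (y2 - y1) / image_size)
            items.append(LabeledImage(img, [box]))
    names = [f"sheep_{c:02d}" for c in range(n_classes)]
    if out_dir is not None:
        save_dataset(items, out_dir, n_classes, names)
    return split_dataset(items, seed=seed, nc=n_classes, class_names=names)
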