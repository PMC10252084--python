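"""Loss, target assignment, detection metrics and the desk-scale training
loop.

Metrics follow the standard detection definitions: precision TP/(TP+FP),
recall TP/(TP+FN), F1 the harmonic mean, AP the area under the
monotone-envelope precision-recall curve, and mAP@0.5 the mean per-class
AP with a 0.5 IoU match threshold.

The objective is the YOLOv5-family composite: a CIoU box term, an
objectness BCE with IoU-weighted targets, and a per-class BCE; anchors
are matched by size ratio (< 4) and each target is assigned to its cell
plus the two nearest neighbouring cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autograd import Tensor, no_grad
from .data import DatasetIndex, LabeledImage, letterbox, mosaic4, apply_letterbox_to_box
from .models import (Detection, Detector, ModelConfig, box_iou_xyxy,
                     decode_predictions, nms, save_checkpoint)

__all__ = [
    "MatchResult", "EvalSummary", "match_detections", "precision", "recall",
    "f1_score", "average_precision", "map50", "compute_loss", "train",
    "evaluate",
]


# ------------------------------------------------------------------ metrics --

@dataclass
class MatchResult:
    """Per-detection TP/FP flags (confidence-ordered) plus the FN count."""

    tp_flags: list[bool]
    confidences: list[float]
    fn: int
    n_truth: int

    @property
    def tp(self) -> int:
        return sum(self.tp_flags)

    @property
    def fp(self) -> int:
        return len(self.tp_flags) - self.tp


@dataclass
class EvalSummary:
    precision: float
    recall: float
    f1: float
    per_class_ap: dict[int, float]
    map50: float

    def __post_init__(self):
        for v in (self.precision, self.recall, self.f1, self.map50):
            if not 0 <= v <= 1 + 1e-9:
                raise ValueError("metric outside [0, 1]")


def match_detections(dets: list[Detection], truths, iou_thr: float = 0.5) -> MatchResult:
    """Greedy matching: detections in descending confidence, each matched
    to the highest-IoU unmatched same-class truth with IoU >= threshold."""
    truths = list(truths)
    dets = sorted(dets, key=lambda d: -d.confidence)
    used = [False] * len(truths)
    flags, confs = [], []
    for d in dets:
        best, best_iou = -1, iou_thr
        for t_idx, (cid, box) in enumerate(truths):
            if used[t_idx] or cid != d.class_id:
                continue
            iou = box_iou_xyxy(np.array(d.box), np.array(box))[0, 0]
            if iou >= best_iou:
                best, best_iou = t_idx, iou
        if best >= 0:
            used[best] = True
            flags.append(True)
        else:
            flags.append(False)
        confs.append(d.confidence)
    return MatchResult(flags, confs, fn=used.count(False), n_truth=len(truths))


def precision(tp: int, fp: int) -> float:
    if tp < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    return tp / (tp + fp) if tp + fp else 0.0


def recall(tp: int, fn: int) -> float:
    if tp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    return tp / (tp + fn) if tp + fn else 0.0


def f1_score(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if p + r else 0.0


def average_precision(confidences, tp_flags, n_truth: int) -> float:
    """Area under the monotone precision envelope over recall, integrated
    with the trapezoidal rule (continuous interpolation)."""
    if n_truth < 1:
        raise ValueError("average_precision needs at least one ground truth")
    conf = np.asarray(confidences, dtype=float)
    tp = np.asarray(tp_flags, dtype=float)
    if conf.size == 0:
        return 0.0
    order = np.argsort(-conf, kind="stable")
    tp = tp[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    rec = cum_tp / n_truth
    prec = cum_tp / np.maximum(cum_tp + cum_fp, 1e-12)
    mrec = np.concatenate(([0.0], rec, [1.0]))
    mpre = np.concatenate(([1.0], prec, [0.0]))
    mpre = np.flip(np.maximum.accumulate(np.flip(mpre)))
    return float(np.trapezoid(mpre, mrec))


def map50(per_class_ap) -> float:
    vals = list(per_class_ap.values()) if isinstance(per_class_ap, dict) else list(per_class_ap)
    if not vals:
        raise ValueError("mAP over an empty class set")
    return float(np.mean(vals))


# --------------------------------------------------------------------- loss --

def _build_targets(targets: np.ndarray, shapes, anchors, nc: int):
    """YOLOv5-style assignment: per scale, anchors filtered by wh ratio < 4
    and each target routed to its cell plus the two nearest neighbours.

    ``targets``: (M, 6) rows (img, cls, cx, cy, w, h) normalised to [0,1].
    Returns per-scale (b, a, gj, gi, tbox, anch_grid, tcls).
    """
    out = []
    na = 3
    g = 0.5
    offs = np.array([[0, 0], [1, 0], [0, 1], [-1, 0], [0, -1]], dtype=np.float32) * g
    for (ny, nx), anc in zip(shapes, anchors):
        anc_g = np.asarray(anc, dtype=np.float32)  # already grid units
        if targets.size == 0:
            out.append(None)
            continue
        t = targets.copy()
        t[:, 2] *= nx; t[:, 4] *= nx
        t[:, 3] *= ny; t[:, 5] *= ny
        t = np.tile(t[None], (na, 1, 1))                      # (na, M, 6)
        ai = np.tile(np.arange(na, dtype=np.float32)[:, None], (1, targets.shape[0]))
        t = np.concatenate([t, ai[..., None]], axis=2)        # (..., 7)
        r = t[..., 4:6] / anc_g[:, None, :]
        keep = np.maximum(r, 1.0 / r).max(axis=2) < 4.0
        t = t[keep]                                           # (K, 7)
        if t.size == 0:
            out.append(None)
            continue
        gxy = t[:, 2:4]
        gxi = np.array([nx, ny], dtype=np.float32) - gxy
        jk = (gxy % 1 < g) & (gxy > 1)
        lm = (gxi % 1 < g) & (gxi > 1)
        mask = np.stack([np.ones(len(t), dtype=bool),
                         jk[:, 0], jk[:, 1], lm[:, 0], lm[:, 1]])
        t_rep = np.tile(t[None], (5, 1, 1))[mask]
        off_rep = np.tile(offs[:, None, :], (1, len(t), 1))[mask]
        gxy = t_rep[:, 2:4]
        gij = (gxy - off_rep).astype(int)
        gi = np.clip(gij[:, 0], 0, nx - 1)
        gj = np.clip(gij[:, 1], 0, ny - 1)
        out.append((t_rep[:, 0].astype(int), t_rep[:, 6].astype(int), gj, gi,
                    np.concatenate([gxy - np.stack([gi, gj], 1), t_rep[:, 4:6]], 1),
                    anc_g[t_rep[:, 6].astype(int)],
                    t_rep[:, 1].astype(int)))
    return out


def _ciou(pbox: Tensor, tbox: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Complete IoU between predicted (K, 4) xywh tensor and target array."""
    px, py = pbox.narrow(1, 0, 1), pbox.narrow(1, 1, 1)
    pw, ph = pbox.narrow(1, 2, 1), pbox.narrow(1, 3, 1)
    t = np.asarray(tbox, dtype=np.float32)
    tx, ty, tw, th = (t[:, i:i + 1] for i in range(4))
    px1, px2 = px - pw * 0.5, px + pw * 0.5
    py1, py2 = py - ph * 0.5, py + ph * 0.5
    tx1, tx2 = tx - tw / 2, tx + tw / 2
    ty1, ty2 = ty - th / 2, ty + th / 2
    iw = (px2.minimum(tx2) - px1.maximum(tx1)).clamp(0)
    ih = (py2.minimum(ty2) - py1.maximum(ty1)).clamp(0)
    inter = iw * ih
    union = pw * ph + tw * th - inter + eps
    iou = inter / union
    cw = px2.maximum(tx2) - px1.minimum(tx1)
    chh = py2.maximum(ty2) - py1.minimum(ty1)
    c2 = cw * cw + chh * chh + eps
    rho2 = (px - tx) ** 2 + (py - ty) ** 2
    v = (4 / math.pi ** 2) * (Tensor(np.arctan(tw / th)) - (pw / ph.clamp(eps)).arctan()) ** 2
    with_alpha = v.data / (v.data - iou.data + 1 + eps)   # detached weight
    return iou - rho2 / c2 - v * with_alpha


def compute_loss(preds: list[Tensor], targets: np.ndarray, cfg: ModelConfig,
                 input_size: int, box_gain: float = 0.05, obj_gain: float = 1.0,
                 cls_gain: float = 0.5):
    """Composite detection loss over the three scales.

    ``targets`` rows are (image_index, class, cx, cy, w, h) normalised.
    Returns (total: Tensor, components: dict of floats).
    """
    balance = (4.0, 1.0, 0.4)
    shapes = [(p.shape[2], p.shape[3]) for p in preds]
    # anchors are defined at 640-pixel scale; rescale to this input, then
    # express in grid units of each stride
    anchors_px = [np.asarray(a, dtype=np.float32) * (input_size / 640.0)
                  for a in cfg.anchors]
    strides = [input_size // s[1] for s in shapes]
    anchors_grid = [a / st for a, st in zip(anchors_px, strides)]
    assigned = _build_targets(np.asarray(targets, dtype=np.float32).reshape(-1, 6),
                              shapes, anchors_grid, cfg.nc)
    lbox = Tensor(0.0)
    lcls = Tensor(0.0)
    lobj = Tensor(0.0)
    n_assigned = 0
    for i, (p, hit) in enumerate(zip(preds, assigned)):
        n, na, ny, nx, no = p.shape
        tobj = np.zeros((n, na, ny, nx), dtype=np.float32)
        if hit is not None:
            b, a, gj, gi, tbox, anch, tcls = hit
            n_assigned += len(b)
            ps = p[(b, a, gj, gi)]                       # (K, no)
            pxy = ps.narrow(1, 0, 2).sigmoid() * 2.0 - 0.5
            pwh = (ps.narrow(1, 2, 2).sigmoid() * 2.0) ** 2 * Tensor(anch)
            pbox = Tensor.concat([pxy, pwh], axis=1)
            ciou = _ciou(pbox, tbox)
            lbox = lbox + (1.0 - ciou).mean()
            tobj[b, a, gj, gi] = np.clip(ciou.data[:, 0], 0, None)
            if cfg.nc > 1:
                t_cls = np.zeros((len(b), cfg.nc), dtype=np.float32)
                t_cls[np.arange(len(b)), tcls] = 1.0
                lcls = lcls + ps.narrow(1, 5, cfg.nc).bce_with_logits(t_cls)
        lobj = lobj + p[..., 4].bce_with_logits(tobj) * balance[i]
    # upstream convention: per-image mean terms scaled back by batch size
    bs = preds[0].shape[0]
    total = (lbox * box_gain + lobj * obj_gain + lcls * cls_gain) * float(bs)
    comp = {"box": float(lbox.data) * box_gain, "obj": float(lobj.data) * obj_gain,
            "cls": float(lcls.data) * cls_gain, "total": float(total.data),
            "n_assigned": n_assigned}
    if not np.isfinite(comp["total"]):
        raise FloatingPointError(f"non-finite loss: {comp}")
    return total, comp


# ----------------------------------------------------------------- pipeline --

def _prepare(item: LabeledImage, input_size: int):
    """Letterbox one item; returns (CHW float image, (cls, cx, cy, w, h) rows)."""
    img = item.load()
    h, w = img.shape[:2]
    canvas, scale, pad = letterbox(img, input_size)
    rows = []
    for cid, cx, cy, bw, bh in item.boxes:
        box = ((cx - bw / 2) * w, (cy - bh / 2) * h, (cx + bw / 2) * w, (cy + bh / 2) * h)
        x1, y1, x2, y2 = apply_letterbox_to_box(box, scale, pad)
        rows.append((cid, (x1 + x2) / 2 / input_size, (y1 + y2) / 2 / input_size,
                     (x2 - x1) / input_size, (y2 - y1) / input_size))
    chw = canvas.astype(np.float32).transpose(2, 0, 1) / 255.0
    return chw, rows


def predict_images(model: Detector, images, input_size: int,
                   conf_thr: float = 0.25, iou_thr: float = 0.45):
    """Detect faces on raw images; boxes returned in original pixel space."""
    model.eval()
    out = []
    for img in images:
        h, w = img.shape[:2]
        canvas, scale, pad = letterbox(img, input_size)
        x = Tensor(canvas.astype(np.float32).transpose(2, 0, 1)[None] / 255.0)
        with no_grad():
            preds = model(x)
        dets = decode_predictions(preds, model.cfg, conf_thr=conf_thr)[0]
        dets = nms(dets, iou_thr=iou_thr, conf_thr=conf_thr)
        mapped = []
        for d in dets:
            from .data import invert_letterbox_on_box
            x1, y1, x2, y2 = invert_letterbox_on_box(d.box, scale, pad)
            x1, x2 = np.clip([x1, x2], 0, w)
            y1, y2 = np.clip([y1, y2], 0, h)
            if x2 > x1 and y2 > y1:
                mapped.append(Detection(d.class_id, d.confidence,
                                        (float(x1), float(y1), float(x2), float(y2))))
        out.append(mapped)
    return out


def evaluate(model: Detector, items: list[LabeledImage], input_size: int = 96,
             iou_thr: float = 0.5, conf_thr_pr: float = 0.25,
             conf_thr_ap: float = 0.001) -> EvalSummary:
    """mAP@0.5 (low-confidence detection set) plus precision/recall/F1 at
    the standard 0.25 reporting threshold."""
    per_class: dict[int, dict] = {}
    tp_hi = fp_hi = fn_hi = 0
    all_dets = predict_images(model, [it.load() for it in items], input_size,
                              conf_thr=conf_thr_ap, iou_thr=0.45)
    for item, dets in zip(items, all_dets):
        h, w = item.load().shape[:2]
        truths = []
        for cid, cx, cy, bw, bh in item.boxes:
            truths.append((cid, ((cx - bw / 2) * w, (cy - bh / 2) * h,
                                 (cx + bw / 2) * w, (cy + bh / 2) * h)))
            per_class.setdefault(cid, {"conf": [], "tp": [], "n": 0})["n"] += 1
        res = match_detections(dets, truths, iou_thr)
        order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
        for rank, i in enumerate(order):
            d = dets[i]
            rec = per_class.setdefault(d.class_id, {"conf": [], "tp": [], "n": 0})
            rec["conf"].append(d.confidence)
            rec["tp"].append(res.tp_flags[rank])
        hi = [d for d in dets if d.confidence >= conf_thr_pr]
        res_hi = match_detections(hi, truths, iou_thr)
        tp_hi += res_hi.tp
        fp_hi += res_hi.fp
        fn_hi += res_hi.fn
    ap = {}
    for cid, rec in per_class.items():
        if rec["n"] == 0:
            continue  # class never appears in the ground truth: skipped
        ap[cid] = average_precision(rec["conf"], rec["tp"], rec["n"])
    p = precision(tp_hi, fp_hi)
    r = recall(tp_hi, fn_hi)
    return EvalSummary(p, r, f1_score(p, r), ap, map50(ap) if ap else 0.0)


# ------------------------------------------------------------------- training --

def estimate_anchors_for(dataset: DatasetIndex, seed: int = 0) -> tuple:
    """Adaptive anchors: IoU k-means + mutation over the training boxes,
    expressed in the 640-pixel reference frame, grouped 3 per scale."""
    from .data import kmeans_anchors
    wh = [(bw * 640.0, bh * 640.0) for it in dataset.train
          for _, _, _, bw, bh in it.boxes]
    a = kmeans_anchors(wh, k=9, generations=150, seed=seed)
    return tuple(tuple(map(tuple, a.reshape(3, 3, 2))))


def train(model_or_cfg, dataset: DatasetIndex, epochs: int = 50,
          lr: float = 0.001, batch_size: int = 16, input_size: int = 96,
          seed: int = 0, momentum: float = 0.937, weight_decay: float = 5e-4,
          warmup_epochs: int = 2, mosaic: bool = True, auto_anchors: bool = False,
          eval_every: int = 0, out_dir=None, verbose: bool = False,
          model_seed: int | None = None):
    """SGD training loop; deterministic given the seed.

    ``auto_anchors`` re-estimates the anchor priors from the training
    boxes (the adaptive anchor-box step of the input pipeline); it is off
    by default so profiling configurations keep the stock priors.

    Returns (model, history) where history is one dict per epoch with the
    averaged loss components (and val mAP@0.5 when ``eval_every`` divides
    the epoch).  The best-mAP checkpoint is written to ``out_dir`` when
    both ``out_dir`` and ``eval_every`` are set.
    """
    if not dataset.train:
        raise ValueError("empty training split")
    if isinstance(model_or_cfg, Detector):
        model = model_or_cfg
        if auto_anchors:
            raise ValueError("auto_anchors requires a config, not a built model")
    else:
        cfg = model_or_cfg
        if auto_anchors and sum(len(it.boxes) for it in dataset.train) >= 9:
            cfg = ModelConfig.from_dict({**cfg.to_dict(),
                                         "anchors": estimate_anchors_for(dataset, seed)})
        model = Detector(cfg, seed=model_seed if model_seed is not None else seed)
    rng = np.random.default_rng(seed)
    cache = [_prepare(it, input_size) for it in dataset.train]
    params = list(model.parameters())
    velocity = [np.zeros_like(p.data) for p in params]
    history = []
    best_map, best_path = -1.0, None
    n_batches = max(1, math.ceil(len(cache) / batch_size))
    total_steps = epochs * n_batches
    step = 0
    for epoch in range(epochs):
        model.train()
        order = rng.permutation(len(cache))
        sums: dict[str, float] = {}
        for bi in range(n_batches):
            idx = order[bi * batch_size:(bi + 1) * batch_size]
            if idx.size == 0:
                continue
            imgs, rows = [], []
            for j, k in enumerate(idx):
                if mosaic and rng.random() < 0.5 and len(cache) >= 4:
                    picks = rng.choice(len(dataset.train), 4, replace=False)
                    m = mosaic4([dataset.train[q] for q in picks], rng, input_size)
                    chw = m.image.astype(np.float32).transpose(2, 0, 1) / 255.0
                    rws = [(cid, cx, cy, w_, h_) for cid, cx, cy, w_, h_ in m.boxes]
                else:
                    chw, rws = cache[k]
                imgs.append(chw)
                rows += [(j, cid, cx, cy, w_, h_) for cid, cx, cy, w_, h_ in rws]
            x = Tensor(np.stack(imgs))
            preds = model(x)
            targets = np.array(rows, dtype=np.float32).reshape(-1, 6)
            loss, comp = compute_loss(preds, targets, model.cfg, input_size)
            for p in params:
                p.grad = None
            loss.backward()
            # linear warmup then cosine decay to 10% of the peak rate
            warm = total_steps and min(1.0, (step + 1) / max(1, warmup_epochs * n_batches))
            cos = 0.5 * (1 + math.cos(math.pi * step / max(1, total_steps)))
            cur_lr = lr * warm * (0.1 + 0.9 * cos)
            for p, v in zip(params, velocity):
                g = p.grad if p.grad is not None else 0.0
                if p.data.ndim == 4:      # weight decay on conv kernels only
                    g = g + weight_decay * p.data
                v *= momentum
                v -= cur_lr * g
                p.data += v
            step += 1
            for k_, v_ in comp.items():
                sums[k_] = sums.get(k_, 0.0) + v_
        entry = {k_: v_ / n_batches for k_, v_ in sums.items()}
        entry["epoch"] = epoch
        entry["lr"] = cur_lr
        if eval_every and ((epoch + 1) % eval_every == 0 or epoch == epochs - 1):
            val_items = dataset.val or dataset.train
            summary = evaluate(model, val_items, input_size)
            entry["val_map50"] = summary.map50
            if out_dir is not None and summary.map50 > best_map:
                best_map = summary.map50
                best_path = Path(out_dir) / "best.npz"
                Path(out_dir).mkdir(parents=True, exist_ok=True)
                save_checkpoint(model, best_path, extra={"epoch": epoch,
                                                         "map50": best_map})
        history.append(entry)
        if verbose:
            msg = ", ".join(f"{k_}={v_:.4f}" for k_, v_ in entry.items()
                            if isinstance(v_, float))
            print(f"epoch {epoch + 1}/{epochs}: {msg}")
    if out_dir is not None and best_path is None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        save_checkpoint(model, Path(out_dir) / "last.npz",
                        extra={"epoch": epochs - 1})
    return model, history
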