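"""Model assembly: the YOLOv5s-v6.1-style baseline and its lightweight
variants, plus prediction decoding and non-maximum suppression.

The baseline layout (width multiple 0.5, depth multiple 0.33) is a 6x6
stem convolution, four stride-2 downsampling stages interleaved with C3
stacks, SPPF, an FPN+PAN neck and a three-scale detection head.  Variant
switches swap in lightweight blocks:

* ``shufflenet_backbone`` — the four stride-2 CBS downsamples become
  ShuffleNetv2 downsampling units (the stem is retained);
* ``ghost_neck`` / ``ghost_backbone`` — every CBS becomes a GhostConv and
  every C3 a C3Ghost in the respective part;
* ``attention`` — a CA/SE/ECA/CBAM gate inserted immediately in front of
  SPPF.

The flagship lightweight configuration (ShuffleNetv2 backbone + ghost
neck + coordinate attention) is available as the ``lsr_yolo`` preset.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import blocks as B
from .autograd import Tensor, no_grad

__all__ = [
    "ModelConfig", "Detection", "Detector", "build_model", "decode_predictions",
    "nms", "box_iou_xyxy", "PRESETS", "save_checkpoint", "load_checkpoint",
]

# COCO anchor priors of the upstream detector (pixels at 640), one triple
# per output stride {8, 16, 32}.
DEFAULT_ANCHORS = (
    ((10, 13), (16, 30), (33, 23)),
    ((30, 61), (62, 45), (59, 119)),
    ((116, 90), (156, 198), (373, 326)),
)

ATTENTION_KINDS = ("none", "ca", "se", "eca", "cbam")


def make_divisible(x: float, d: int = 8) -> int:
    return max(d, int(math.ceil(x / d) * d))


@dataclass
class ModelConfig:
    """Variant switches and head geometry for one detector build."""

    nc: int = 63
    width_multiple: float = 0.5
    depth_multiple: float = 0.33
    ghost_neck: bool = False
    ghost_backbone: bool = False
    shufflenet_backbone: bool = False
    attention: str = "none"
    anchors: tuple = DEFAULT_ANCHORS
    input_size: int = 640
    ca_calibrated: bool = True

    def __post_init__(self):
        if self.nc < 1:
            raise ValueError("nc must be >= 1")
        if self.width_multiple <= 0 or self.depth_multiple <= 0:
            raise ValueError("width/depth multiples must be positive")
        if self.attention not in ATTENTION_KINDS:
            raise ValueError(f"attention must be one of {ATTENTION_KINDS}")
        if self.ghost_backbone and self.shufflenet_backbone:
            raise ValueError("ghost_backbone and shufflenet_backbone are "
                             "mutually exclusive")
        a = np.asarray(self.anchors, dtype=float)
        if a.shape != (3, 3, 2):
            raise ValueError("anchors must be 3 scales x 3 (w, h) pairs")
        areas = a.prod(axis=2).mean(axis=1)
        if not (areas[0] <= areas[1] <= areas[2]):
            raise ValueError("anchor scales must be sorted by area")
        self.anchors = tuple(tuple(tuple(float(v) for v in wh) for wh in scale)
                             for scale in a)

    # ------------------------------------------------------------- serde
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["anchors"] = [[list(wh) for wh in s] for s in self.anchors]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: Named variants matching the ablation grid.
PRESETS: dict[str, dict] = {
    "yolov5s": {},
    "ghost_neck": {"ghost_neck": True},
    "ghost_backbone": {"ghost_backbone": True},
    "ghost_all": {"ghost_neck": True, "ghost_backbone": True},
    "shufflenetv2": {"shufflenet_backbone": True},
    "lsr_yolo": {"ghost_neck": True, "shufflenet_backbone": True,
                 "attention": "ca"},
}


@dataclass
class Detection:
    """One predicted box in input-pixel coordinates."""

    class_id: int
    confidence: float
    box: tuple[float, float, float, float]  # x1, y1, x2, y2

    def __post_init__(self):
        x1, y1, x2, y2 = self.box
        if not (x2 > x1 and y2 > y1):
            raise ValueError(f"degenerate box {self.box}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


class Detector(B.Module):
    """The assembled detector: backbone, neck and three-scale head."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        w, dm = cfg.width_multiple, cfg.depth_multiple

        def ch(c):  # scaled channel count
            return make_divisible(c * w)

        def depth(n):
            return max(round(n * dm), 1)

        c0, c1, c2, c3_, c4 = ch(64), ch(128), ch(256), ch(512), ch(1024)
        gn, gb, sh = cfg.ghost_neck, cfg.ghost_backbone, cfg.shufflenet_backbone

        def bb_down(ci, co):
            if sh:
                return B.ShuffleUnit(ci, co, s=2, rng=rng)
            if gb:
                return B.GhostConv(ci, co, 3, 2, rng=rng)
            return B.Conv(ci, co, 3, 2, rng=rng)

        def bb_c3(c, n):
            k = B.C3Ghost if gb else B.C3
            return k(c, c, depth(n), rng=rng)

        def nk_conv(ci, co, k, s):
            if gn:
                return B.GhostConv(ci, co, k, s, rng=rng)
            return B.Conv(ci, co, k, s, rng=rng)

        def nk_c3(ci, co):
            k = B.C3Ghost if gn else B.C3
            return k(ci, co, depth(3), shortcut=False, rng=rng)

        self.stem = B.Conv(3, c0, 6, 2, 2, rng=rng)              # P1/2
        self.down1, self.c3_1 = bb_down(c0, c1), bb_c3(c1, 3)    # P2/4
        self.down2, self.c3_2 = bb_down(c1, c2), bb_c3(c2, 6)    # P3/8
        self.down3, self.c3_3 = bb_down(c2, c3_), bb_c3(c3_, 9)  # P4/16
        self.down4, self.c3_4 = bb_down(c3_, c4), bb_c3(c4, 3)   # P5/32
        self.attn = (None if cfg.attention == "none"
                     else B.make_attention(cfg.attention, c4, rng=rng,
                                           calibrated=cfg.ca_calibrated))
        self.sppf = B.SPPF(c4, c4, rng=rng)

        self.n_conv1 = nk_conv(c4, c3_, 1, 1)
        self.n_c3_1 = nk_c3(c4, c3_)       # after concat with P4 (c3_+c3_)
        self.n_conv2 = nk_conv(c3_, c2, 1, 1)
        self.n_c3_2 = nk_c3(c3_, c2)       # after concat with P3 -> P3 out
        self.n_conv3 = nk_conv(c2, c2, 3, 2)
        self.n_c3_3 = nk_c3(c3_, c3_)      # concat with n_conv2 out -> P4 out
        self.n_conv4 = nk_conv(c3_, c3_, 3, 2)
        self.n_c3_4 = nk_c3(c4, c4)        # concat with n_conv1 out -> P5 out

        no = 3 * (cfg.nc + 5)
        self.head = [B.Conv(c, no, 1, act=False, bn=False, bias=True, rng=rng)
                     for c in (c2, c3_, c4)]
        self.strides = (8, 16, 32)
        self.head_channels = (c2, c3_, c4)
        self._init_head_biases()

    def _init_head_biases(self):
        """Prior-probability bias initialisation of the detection convs."""
        nc = self.cfg.nc
        for conv, s in zip(self.head, self.strides):
            b = conv.bias.data.reshape(3, nc + 5)
            b[:, 4] += math.log(8 / (640 / s) ** 2)   # ~8 objects per image
            b[:, 5:] += math.log(0.6 / (nc - 0.99)) if nc > 1 else 0.0
            conv.bias.data = b.reshape(-1)

    # ------------------------------------------------------------ forward
    def forward(self, x: Tensor) -> list[Tensor]:
        """Raw multi-scale predictions.

        Input: (N, 3, S, S) with S divisible by 32.  Output: one tensor
        per stride in {8, 16, 32}, shaped (N, 3, S/stride, S/stride, nc+5).
        """
        s = x.shape[-1]
        if x.shape[-1] % 32 or x.shape[-2] % 32:
            raise ValueError(f"input size {x.shape[-2:]}, must be divisible by 32")
        y = self.stem(x)
        y = self.c3_1(self.down1(y))
        p3 = self.c3_2(self.down2(y))
        p4 = self.c3_3(self.down3(p3))
        y = self.c3_4(self.down4(p4))
        if self.attn is not None:
            y = self.attn(y)
        p5 = self.sppf(y)

        t1 = self.n_conv1(p5)
        y = self.n_c3_1(Tensor.concat([t1.upsample2x(), p4], axis=1))
        t2 = self.n_conv2(y)
        out3 = self.n_c3_2(Tensor.concat([t2.upsample2x(), p3], axis=1))
        out4 = self.n_c3_3(Tensor.concat([self.n_conv3(out3), t2], axis=1))
        out5 = self.n_c3_4(Tensor.concat([self.n_conv4(out4), t1], axis=1))

        outs = []
        nc5 = self.cfg.nc + 5
        for conv, feat in zip(self.head, (out3, out4, out5)):
            raw = conv(feat)
            n, _, ny, nx = raw.shape
            outs.append(raw.reshape(n, 3, nc5, ny, nx).transpose(0, 1, 3, 4, 2))
        return outs

    # ------------------------------------------------------------ profile
    def profile(self, shape, acc, name="model"):
        c, h, w = shape
        s = self.stem.profile(shape, acc, "stem")
        s = self.down1.profile(s, acc, "down1")
        s = self.c3_1.profile(s, acc, "c3_1")
        s = self.down2.profile(s, acc, "down2")
        p3 = self.c3_2.profile(s, acc, "c3_2")
        s = self.down3.profile(p3, acc, "down3")
        p4 = self.c3_3.profile(s, acc, "c3_3")
        s = self.down4.profile(p4, acc, "down4")
        s = self.c3_4.profile(s, acc, "c3_4")
        if self.attn is not None:
            s = self.attn.profile(s, acc, "attn")
        p5 = self.sppf.profile(s, acc, "sppf")

        t1 = self.n_conv1.profile(p5, acc, "n_conv1")
        up1 = (t1[0] + p4[0], p4[1], p4[2])
        s = self.n_c3_1.profile(up1, acc, "n_c3_1")
        t2 = self.n_conv2.profile(s, acc, "n_conv2")
        up2 = (t2[0] + p3[0], p3[1], p3[2])
        o3 = self.n_c3_2.profile(up2, acc, "n_c3_2")
        d3 = self.n_conv3.profile(o3, acc, "n_conv3")
        o4 = self.n_c3_3.profile((d3[0] + t2[0], d3[1], d3[2]), acc, "n_c3_3")
        d4 = self.n_conv4.profile(o4, acc, "n_conv4")
        o5 = self.n_c3_4.profile((d4[0] + t1[0], d4[1], d4[2]), acc, "n_c3_4")
        for conv, feat, nm in zip(self.head, (o3, o4, o5), ("p3", "p4", "p5")):
            conv.profile(feat, acc, f"head.{nm}")
        return o5


def build_model(cfg: ModelConfig | str | dict, seed: int = 0) -> Detector:
    """Build a detector from a config object, preset name or dict."""
    if isinstance(cfg, str):
        if cfg not in PRESETS:
            raise ValueError(f"unknown preset {cfg!r}; choose from {sorted(PRESETS)}")
        cfg = ModelConfig(**PRESETS[cfg])
    elif isinstance(cfg, dict):
        cfg = ModelConfig.from_dict(cfg)
    return Detector(cfg, seed=seed)


# ------------------------------------------------------------------ decode --

def decode_predictions(raw: list, cfg: ModelConfig,
                       conf_thr: float = 0.25) -> list[list[Detection]]:
    """Decode raw head outputs into per-image pixel-space detections.

    Center offsets decode as (2*sigmoid(t) - 0.5 + cell) * stride and
    sizes as (2*sigmoid(t))^2 * anchor, the convention the head was
    trained with; confidence is objectness times the best class score.
    """
    arrays = [r.data if isinstance(r, Tensor) else np.asarray(r) for r in raw]
    n = arrays[0].shape[0]
    out: list[list[Detection]] = [[] for _ in range(n)]
    for scale, pred in enumerate(arrays):
        stride = 8 * 2 ** scale
        _, na, ny, nx, _ = pred.shape
        # anchors are pixel priors at the 640 reference size; rescale to
        # the actual input (nx * stride) so training and decoding agree
        anchors = np.asarray(cfg.anchors[scale], dtype=np.float32) * (nx * stride / 640.0)
        sig = 1.0 / (1.0 + np.exp(-pred))
        gy, gx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        cx = (sig[..., 0] * 2.0 - 0.5 + gx) * stride
        cy = (sig[..., 1] * 2.0 - 0.5 + gy) * stride
        pw = (sig[..., 2] * 2.0) ** 2 * anchors[None, :, None, None, 0]
        ph = (sig[..., 3] * 2.0) ** 2 * anchors[None, :, None, None, 1]
        obj = sig[..., 4]
        cls = sig[..., 5:]
        cid = cls.argmax(axis=-1)
        conf = obj * np.take_along_axis(cls, cid[..., None], axis=-1)[..., 0]
        keep = conf >= conf_thr
        for img, a, yy, xx in zip(*np.nonzero(keep)):
            w2, h2 = pw[img, a, yy, xx] / 2, ph[img, a, yy, xx] / 2
            box = (float(cx[img, a, yy, xx] - w2), float(cy[img, a, yy, xx] - h2),
                   float(cx[img, a, yy, xx] + w2), float(cy[img, a, yy, xx] + h2))
            if box[2] <= box[0] or box[3] <= box[1]:
                continue
            out[img].append(Detection(int(cid[img, a, yy, xx]),
                                      float(min(conf[img, a, yy, xx], 1.0)), box))
    return out


def box_iou_xyxy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (N, 4) and (M, 4) corner-format boxes."""
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / union, 0.0)


def nms(dets: list[Detection], iou_thr: float = 0.45,
        conf_thr: float = 0.25) -> list[Detection]:
    """Greedy per-class non-maximum suppression by descending confidence."""
    if not 0 <= iou_thr <= 1 or not 0 <= conf_thr <= 1:
        raise ValueError("thresholds must lie in [0, 1]")
    dets = [d for d in dets if d.confidence >= conf_thr]
    keep: list[Detection] = []
    for cid in sorted({d.class_id for d in dets}):
        group = sorted((d for d in dets if d.class_id == cid),
                       key=lambda d: -d.confidence)
        boxes = np.array([d.box for d in group])
        alive = np.ones(len(group), dtype=bool)
        for i in range(len(group)):
            if not alive[i]:
                continue
            keep.append(group[i])
            if i + 1 < len(group):
                ious = box_iou_xyxy(boxes[i], boxes[i + 1:])[0]
                alive[i + 1:] &= ious < iou_thr
    return sorted(keep, key=lambda d: -d.confidence)


# -------------------------------------------------------------- checkpoint --

def save_checkpoint(model: Detector, path, extra: dict | None = None) -> None:
    """Single-file .npz checkpoint: config JSON + named params + BN stats."""
    arrays = {f"param/{k}": v.data for k, v in model.named_parameters()}
    arrays.update({f"buffer/{k}": v for k, v in model.buffers()})
    meta = {"config": model.cfg.to_dict(), "extra": extra or {}}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> Detector:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"].tobytes()).decode())
        model = build_model(ModelConfig.from_dict(meta["config"]))
        params = dict(model.named_parameters())
        for key in z.files:
            if key.startswith("param/"):
                params[key[6:]].data = z[key].astype(np.float32)
        bufs = dict(model.buffers())
        for key in z.files:
            if key.startswith("buffer/"):
                bufs[key[7:]][...] = z[key]
    return model
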