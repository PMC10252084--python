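"""scikit-learn-style estimator facade over the detection pipeline.

``SheepFaceDetector`` follows the estimator protocol (``get_params`` /
``set_params`` / ``fit`` / ``predict`` / ``score``) so it composes with
sklearn model-selection utilities; the heavy lifting lives in the
``models`` and ``train_eval`` modules.
"""

from __future__ import annotations

import numpy as np

from .data import DatasetIndex, LabeledImage, split_dataset
from .models import Detection, ModelConfig, PRESETS, build_model
from .train_eval import evaluate, predict_images, train

__all__ = ["SheepFaceDetector"]


class SheepFaceDetector:
    """Single-stage sheep-face detector with selectable lightweight variants.

    Parameters
    ----------
    variant:
        Preset name: ``yolov5s``, ``ghost_neck``, ``ghost_backbone``,
        ``ghost_all``, ``shufflenetv2`` or ``lsr_yolo`` (ShuffleNetv2
        backbone + ghost neck + coordinate attention).
    nc:
        Number of identity classes.
    input_size:
        Square training/inference resolution (divisible by 32).
    epochs, lr, batch_size, mosaic:
        Training-loop settings (see ``train_eval.train``).
    auto_anchors:
        Re-estimate anchor priors from the training boxes before fitting
        (the adaptive anchor-box step of the input pipeline); on by
        default here, off in the lower-level ``train``.
    conf_thr, iou_thr:
        Decoding confidence threshold and NMS IoU threshold.
    seed:
        Controls weight init, data shuffling and mosaic sampling.

    Attributes (after ``fit``)
    --------------------------
    model_ : the trained ``Detector``
    history_ : list of per-epoch loss/metric dicts
    classes_ : ndarray of class ids
    """

    def __init__(self, variant: str = "lsr_yolo", nc: int = 5,
                 input_size: int = 96, epochs: int = 30, lr: float = 0.001,
                 batch_size: int = 16, mosaic: bool = True,
                 auto_anchors: bool = True, conf_thr: float = 0.25,
                 iou_thr: float = 0.45, seed: int = 0):
        self.variant = variant
        self.nc = nc
        self.input_size = input_size
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.mosaic = mosaic
        self.auto_anchors = auto_anchors
        self.conf_thr = conf_thr
        self.iou_thr = iou_thr
        self.seed = seed

    # ----------------------------------------------------- sklearn protocol
    _param_names = ("variant", "nc", "input_size", "epochs", "lr",
                    "batch_size", "mosaic", "auto_anchors", "conf_thr",
                    "iou_thr", "seed")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "SheepFaceDetector":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self) -> ModelConfig:
        if self.variant not in PRESETS:
            raise ValueError(f"unknown variant {self.variant!r}")
        return ModelConfig(nc=self.nc, input_size=self.input_size,
                           **PRESETS[self.variant])

    # ------------------------------------------------------------------ fit
    def fit(self, X, y=None) -> "SheepFaceDetector":
        """Train on labelled images.

        ``X`` is a ``DatasetIndex`` or a flat list of ``LabeledImage``
        (split 8-1-1 internally); ``y`` is ignored (labels travel with the
        images, as is usual for detection)."""
        if isinstance(X, DatasetIndex):
            ds = X
        else:
            items = list(X)
            if not all(isinstance(it, LabeledImage) for it in items):
                raise TypeError("X must contain LabeledImage items")
            ds = split_dataset(items, seed=self.seed, nc=self.nc)
        self.model_, self.history_ = train(
            self._config(), ds, epochs=self.epochs, lr=self.lr,
            batch_size=self.batch_size, input_size=self.input_size,
            seed=self.seed, mosaic=self.mosaic, auto_anchors=self.auto_anchors)
        self.classes_ = np.arange(self.nc)
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this SheepFaceDetector instance is not fitted yet")

    def predict(self, X) -> list[list[Detection]]:
        """Detections for each image (H x W x 3 uint8 arrays or
        ``LabeledImage``), boxes in original pixel coordinates."""
        self._check_fitted()
        imgs = [x.load() if isinstance(x, LabeledImage) else np.asarray(x)
                for x in X]
        return predict_images(self.model_, imgs, self.input_size,
                              conf_thr=self.conf_thr, iou_thr=self.iou_thr)

    def score(self, X, y=None) -> float:
        """mAP@0.5 on labelled images."""
        self._check_fitted()
        items = [x if isinstance(x, LabeledImage) else LabeledImage(*x) for x in X]
        return evaluate(self.model_, items, self.input_size).map50
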