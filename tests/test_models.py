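"""Model assembly contracts: head geometry, variant interface parity,
decoding closed forms, NMS and checkpoint round-trips."""

import numpy as np
import pytest

from sheepface.autograd import Tensor, no_grad
from sheepface.models import (Detection, ModelConfig, PRESETS, build_model,
                              decode_predictions, load_checkpoint, nms,
                              save_checkpoint)


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(nc=0)
    with pytest.raises(ValueError):
        ModelConfig(ghost_backbone=True, shufflenet_backbone=True)
    with pytest.raises(ValueError):
        ModelConfig(attention="nope")
    # anchors must be sorted by scale area
    bad = (((116, 90), (156, 198), (373, 326)),
           ((30, 61), (62, 45), (59, 119)),
           ((10, 13), (16, 30), (33, 23)))
    with pytest.raises(ValueError):
        ModelConfig(anchors=bad)


def test_head_channels_follow_class_count():
    m = build_model(ModelConfig(nc=1, input_size=64))
    assert all(conv.c2 == 3 * (1 + 5) for conv in m.head)
    m63 = build_model(ModelConfig(nc=63))
    assert all(conv.c2 == 3 * 68 for conv in m63.head)


def test_forward_grid_shapes_and_stride_arithmetic():
    cfg = ModelConfig(nc=2, input_size=64, ghost_neck=True,
                      shufflenet_backbone=True, attention="ca")
    m = build_model(cfg).eval()
    with no_grad():
        outs = m(Tensor(np.zeros((1, 3, 64, 64), dtype=np.float32)))
    assert [o.shape for o in outs] == [(1, 3, 8, 8, 7), (1, 3, 4, 4, 7),
                                      (1, 3, 2, 2, 7)]
    with no_grad():
        outs = m(Tensor(np.zeros((1, 3, 96, 96), dtype=np.float32)))
    assert [o.shape[2] for o in outs] == [12, 6, 3]
    with pytest.raises(ValueError):
        m(Tensor(np.zeros((1, 3, 60, 60), dtype=np.float32)))


def test_all_variants_share_output_interface(tiny_dataset):
    x = Tensor(np.random.default_rng(0).random((1, 3, 64, 64)).astype(np.float32))
    shapes = set()
    for name in PRESETS:
        m = build_model(ModelConfig(nc=2, input_size=64, **PRESETS[name])).eval()
        with no_grad():
            outs = m(x)
        shapes.add(tuple(o.shape for o in outs))
    assert len(shapes) == 1  # substitutions are interface-preserving


def test_decode_closed_forms():
    """All-zero logits put the center at the cell center and reproduce the
    anchor size exactly (2*sigmoid(0) = 1)."""
    cfg = ModelConfig(nc=1, input_size=640)
    raw = [np.full((1, 3, 640 // s, 640 // s, 6), -20.0, dtype=np.float32)
           for s in (8, 16, 32)]
    # one confident cell at scale 0, anchor 0 (anchor (10, 13)), cell (0, 0)
    raw[0][0, 0, 0, 0] = [0.0, 0.0, 0.0, 0.0, 20.0, 20.0]
    dets = decode_predictions(raw, cfg, conf_thr=0.5)[0]
    assert len(dets) == 1
    d = dets[0]
    x1, y1, x2, y2 = d.box
    # center offset 2*sigmoid(0) - 0.5 = 0.5 cells -> pixel 4 at stride 8
    assert (x1 + x2) / 2 == pytest.approx(4.0)
    assert (y1 + y2) / 2 == pytest.approx(4.0)
    assert x2 - x1 == pytest.approx(10.0)  # (2*sigmoid(0))^2 * 10
    assert y2 - y1 == pytest.approx(13.0)
    assert d.confidence == pytest.approx(1.0, abs=1e-4)


def test_decode_forward_deterministic():
    cfg = ModelConfig(nc=2, input_size=64)
    m = build_model(cfg, seed=5).eval()
    x = Tensor(np.random.default_rng(1).random((1, 3, 64, 64)).astype(np.float32))
    with no_grad():
        a = decode_predictions(m(x), cfg, conf_thr=0.0)[0]
        b = decode_predictions(m(x), cfg, conf_thr=0.0)[0]
    assert [(d.class_id, d.confidence, d.box) for d in a] == \
           [(d.class_id, d.confidence, d.box) for d in b]


class TestNMS:
    def test_identical_boxes_keep_highest_confidence(self):
        dets = [Detection(0, 0.9, (0, 0, 10, 10)),
                Detection(0, 0.8, (0, 0, 10, 10))]
        out = nms(dets, iou_thr=0.45, conf_thr=0.1)
        assert len(out) == 1 and out[0].confidence == 0.9

    def test_disjoint_boxes_both_survive(self):
        dets = [Detection(0, 0.9, (0, 0, 10, 10)),
                Detection(0, 0.8, (20, 20, 30, 30))]
        assert len(nms(dets, 0.45, 0.1)) == 2

    def test_iou_boundary_one_third(self):
        # boxes (0,0,10,10) and (5,0,15,10): IoU = 50/150 = 1/3; the weaker
        # box is suppressed exactly when the threshold is <= 1/3
        dets = [Detection(0, 0.9, (0, 0, 10, 10)),
                Detection(0, 0.8, (5, 0, 15, 10))]
        assert len(nms(dets, iou_thr=1 / 3 - 1e-6, conf_thr=0.1)) == 1
        assert len(nms(dets, iou_thr=1 / 3 + 1e-6, conf_thr=0.1)) == 2

    def test_classes_suppressed_independently(self):
        dets = [Detection(0, 0.9, (0, 0, 10, 10)),
                Detection(1, 0.8, (0, 0, 10, 10))]
        assert len(nms(dets, 0.45, 0.1)) == 2

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            nms([], iou_thr=1.5, conf_thr=0.1)


def test_checkpoint_roundtrip(tmp_path):
    cfg = ModelConfig(nc=2, input_size=64, ghost_neck=True)
    m = build_model(cfg, seed=3).eval()
    x = Tensor(np.random.default_rng(2).random((1, 3, 64, 64)).astype(np.float32))
    with no_grad():
        ref = [o.data.copy() for o in m(x)]
    path = tmp_path / "ckpt.npz"
    save_checkpoint(m, path, extra={"note": "roundtrip"})
    m2 = load_checkpoint(path).eval()
    assert m2.cfg.to_dict() == cfg.to_dict()
    with no_grad():
        got = [o.data for o in m2(x)]
    for a, b in zip(ref, got):
        np.testing.assert_allclose(a, b, atol=1e-6)


def test_yaml_roundtrip(tmp_path):
    cfg = ModelConfig(nc=7, attention="se", ghost_neck=True)
    p = tmp_path / "cfg.yaml"
    cfg.to_yaml(p)
    assert ModelConfig.from_yaml(p).to_dict() == cfg.to_dict()
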