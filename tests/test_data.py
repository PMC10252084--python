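"""Dataset pipeline: split arithmetic, augmentation geometry, letterbox
round-trips, mosaic stitching, anchor estimation and the fixture
generator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sheepface.data import (LabeledImage, augment_brightness, augment_rotate45,
                            augment_vflip, generate_fixture_dataset,
                            kmeans_anchors, letterbox, mosaic4, read_labels,
                            invert_letterbox_on_box, apply_letterbox_to_box,
                            split_dataset, write_labels)


def make_items(n, n_classes=10):
    return [LabeledImage(None, [(i % n_classes, 0.5, 0.5, 0.2, 0.2)])
            for i in range(n)]


# -------------------------------------------------------------------- split --

def test_split_exact_table_sizes():
    ds = split_dataset(make_items(12_410, 63), seed=0, nc=63)
    assert (len(ds.train), len(ds.val), len(ds.test)) == (9928, 1241, 1241)


def test_split_small_and_deterministic():
    items = make_items(10, 2)
    ds = split_dataset(items, seed=3, nc=2)
    assert (len(ds.train), len(ds.val), len(ds.test)) == (8, 1, 1)
    ds2 = split_dataset(items, seed=3, nc=2)
    assert [id(x) for x in ds.train] == [id(x) for x in ds2.train]
    assert [id(x) for x in ds.val] == [id(x) for x in ds2.val]


@given(n=st.integers(20, 400), nc=st.integers(2, 8), seed=st.integers(0, 99))
@settings(max_examples=25, deadline=None)
def test_split_partition_properties(n, nc, seed):
    items = make_items(n, nc)
    ds = split_dataset(items, seed=seed, nc=nc)
    assert len(ds.train) + len(ds.val) + len(ds.test) == n
    ids = [id(x) for x in ds.items]
    assert len(set(ids)) == n  # disjoint and exhaustive
    assert len(ds.val) == int(0.1 * n) and len(ds.test) == int(0.1 * n)
    # stratification: every identity keeps at least one training item
    train_classes = {it.boxes[0][0] for it in ds.train}
    assert train_classes == {it.boxes[0][0] for it in items}


def test_split_rejects_tiny_pools():
    with pytest.raises(ValueError):
        split_dataset(make_items(5), seed=0)


# ------------------------------------------------------------- augmentation --

@pytest.fixture()
def checker_item(rng):
    img = rng.integers(0, 255, (64, 80, 3), dtype=np.uint8)
    return LabeledImage(img, [(0, 0.5, 0.2, 0.25, 0.25)])


def test_brightness_identity_and_clipping(checker_item):
    same = augment_brightness(checker_item, 1.0)
    np.testing.assert_array_equal(same.image, checker_item.image)
    bright = augment_brightness(checker_item, 10.0)
    assert bright.image.max() == 255 and bright.boxes == checker_item.boxes


def test_vflip_reflects_cy(checker_item):
    f = augment_vflip(checker_item)
    cid, cx, cy, w, h = f.boxes[0]
    assert (cid, cx, w, h) == (0, 0.5, 0.25, 0.25)
    assert cy == pytest.approx(0.8)
    np.testing.assert_array_equal(f.image, checker_item.image[::-1])


def test_rotate45_centered_square_envelope():
    # a centered axis-aligned square of side s becomes (before clipping) an
    # axis-aligned envelope of side s*sqrt(2)
    img = np.full((200, 200, 3), 50, dtype=np.uint8)
    item = LabeledImage(img, [(0, 0.5, 0.5, 0.3, 0.3)])
    rot = augment_rotate45(item)
    cid, cx, cy, w, h = rot.boxes[0]
    assert (cx, cy) == (pytest.approx(0.5, abs=1e-6), pytest.approx(0.5, abs=1e-6))
    assert w == pytest.approx(0.3 * np.sqrt(2), rel=1e-6)
    assert h == pytest.approx(0.3 * np.sqrt(2), rel=1e-6)


def test_rotate45_label_tracks_pixels():
    """The transformed label must enclose the rotated object pixels."""
    img = np.zeros((128, 128, 3), dtype=np.uint8)
    img[30:50, 80:110] = 255  # bright block, off-center
    cx, cy = 95 / 128, 40 / 128
    item = LabeledImage(img, [(0, cx, cy, 30 / 128, 20 / 128)])
    rot = augment_rotate45(item)
    ys, xs = np.nonzero(rot.image[..., 0] > 200)
    assert len(xs) > 0 and len(rot.boxes) == 1
    _, bcx, bcy, bw, bh = rot.boxes[0]
    x1, x2 = (bcx - bw / 2) * 128, (bcx + bw / 2) * 128
    y1, y2 = (bcy - bh / 2) * 128, (bcy + bh / 2) * 128
    assert x1 - 2 <= xs.min() and xs.max() <= x2 + 2
    assert y1 - 2 <= ys.min() and ys.max() <= y2 + 2


def test_rotate45_drops_out_of_frame_boxes():
    img = np.zeros((100, 100, 3), dtype=np.uint8)
    item = LabeledImage(img, [(0, 0.02, 0.02, 0.03, 0.03)])  # corner box
    rot = augment_rotate45(item)
    assert len(rot.boxes) <= 1  # either clipped-in or dropped, never invalid
    for _, cx, cy, w, h in rot.boxes:
        assert 0 < w <= 1 and 0 < h <= 1
        assert 0 <= cx - w / 2 and cx + w / 2 <= 1


@given(angle=st.sampled_from([45.0]), cx=st.floats(0.25, 0.75),
       cy=st.floats(0.25, 0.75), factor=st.floats(0.4, 1.6))
@settings(max_examples=20, deadline=None)
def test_augmentations_keep_boxes_valid(angle, cx, cy, factor):
    img = np.full((96, 96, 3), 90, dtype=np.uint8)
    item = LabeledImage(img, [(0, cx, cy, 0.2, 0.15)])
    for out in (augment_brightness(item, factor), augment_vflip(item),
                augment_rotate45(item, angle)):
        for _, bx, by, bw, bh in out.boxes:
            assert bw > 0 and bh > 0
            assert 0 <= bx - bw / 2 and bx + bw / 2 <= 1 + 1e-6
            assert 0 <= by - bh / 2 and by + bh / 2 <= 1 + 1e-6


# ---------------------------------------------------------------- letterbox --

def test_letterbox_square_identity(rng):
    img = rng.integers(0, 255, (320, 320, 3), dtype=np.uint8)
    canvas, scale, pad = letterbox(img, 320)
    assert scale == 1.0 and pad == (0, 0)
    np.testing.assert_array_equal(canvas, img)


def test_letterbox_landscape_geometry():
    img = np.zeros((1824, 2736, 3), dtype=np.uint8)
    canvas, scale, pad = letterbox(img, 640)
    assert scale == pytest.approx(640 / 2736)
    assert canvas.shape == (640, 640, 3)
    nh = round(1824 * scale)
    assert pad[0] == 0 and pad[1] == (640 - nh) // 2
    assert 640 - nh == pytest.approx(213, abs=1)  # total vertical padding
    assert canvas[0, 0].tolist() == [114, 114, 114]


def test_letterbox_box_roundtrip(rng):
    img = rng.integers(0, 255, (300, 500, 3), dtype=np.uint8)
    _, scale, pad = letterbox(img, 640)
    box = (37.0, 81.0, 210.0, 229.0)
    fwd = apply_letterbox_to_box(box, scale, pad)
    back = invert_letterbox_on_box(fwd, scale, pad)
    np.testing.assert_allclose(back, box, atol=1.0)


def test_letterbox_rejects_bad_target():
    with pytest.raises(ValueError):
        letterbox(np.zeros((10, 10, 3), dtype=np.uint8), 100)


# ------------------------------------------------------------------- mosaic --

def test_mosaic_four_copies_one_box_per_quadrant(rng):
    img = rng.integers(0, 255, (80, 80, 3), dtype=np.uint8)
    item = LabeledImage(img, [(0, 0.5, 0.5, 0.3, 0.3)])
    m = mosaic4([item] * 4, seed=4, out_size=160)
    assert m.image.shape == (160, 160, 3)
    assert len(m.boxes) == 4
    quadrants = {(cx < 0.5, cy < 0.5) for _, cx, cy, _, _ in m.boxes}
    assert len(quadrants) == 4  # one box per quadrant region


def test_mosaic_never_adds_boxes_and_is_deterministic(tiny_dataset):
    items = tiny_dataset.train[:4]
    a = mosaic4(items, seed=9, out_size=128)
    b = mosaic4(items, seed=9, out_size=128)
    assert len(a.boxes) <= sum(len(i.boxes) for i in items)
    np.testing.assert_array_equal(a.image, b.image)
    assert a.boxes == b.boxes
    with pytest.raises(ValueError):
        mosaic4(items[:3], seed=0)


# ------------------------------------------------------------------ anchors --

def test_kmeans_degenerate_single_size():
    wh = [(32.0, 48.0)] * 40
    anchors = kmeans_anchors(wh, k=9, seed=0)
    np.testing.assert_allclose(anchors, np.tile([32, 48], (9, 1)))


def test_kmeans_sorted_and_recovers_clusters(rng):
    centers = np.array([[20, 24], [80, 70], [220, 260]], dtype=float)
    wh = np.concatenate([c * rng.uniform(0.97, 1.03, (60, 2)) for c in centers])
    anchors = kmeans_anchors(wh, k=3, generations=150, seed=1)
    areas = anchors.prod(axis=1)
    assert np.all(np.diff(areas) >= 0)  # ascending by area
    for c in centers:
        rel = np.abs(anchors - c) / c
        assert rel.min(axis=0).max() < 0.05  # within 5% of generating sizes


def test_kmeans_needs_enough_boxes():
    with pytest.raises(ValueError):
        kmeans_anchors([(10, 10)] * 5, k=9)


# ------------------------------------------------------------------ fixture --

def test_fixture_counts_and_validity(fixture_dataset):
    ds = fixture_dataset
    assert len(ds.items) == 100 and ds.nc == 5
    assert (len(ds.train), len(ds.val), len(ds.test)) == (80, 10, 10)
    for it in ds.items:
        assert it.image.shape == (320, 320, 3) and it.image.dtype == np.uint8
        assert len(it.boxes) >= 1
        for cid, cx, cy, w, h in it.boxes:
            assert 0 <= cid < 5 and w > 0.1 and h > 0.1


def test_fixture_deterministic_on_disk(tmp_path):
    for sub in ("a", "b"):
        generate_fixture_dataset(3, 4, 160, seed=21, out_dir=tmp_path / sub)
    for lbl in sorted((tmp_path / "a" / "labels").iterdir()):
        twin = tmp_path / "b" / "labels" / lbl.name
        assert lbl.read_bytes() == twin.read_bytes()
    imgs_a = sorted((tmp_path / "a" / "images").iterdir())
    assert len(imgs_a) == 12
    first = imgs_a[0]
    assert first.read_bytes() == (tmp_path / "b" / "images" / first.name).read_bytes()


def test_fixture_identities_are_discriminative(fixture_dataset):
    """Mean inter-class distance between face crops exceeds the mean
    intra-class distance: the spot patterns carry identity information."""
    from PIL import Image

    def signature(it):
        h, w = it.image.shape[:2]
        _, cx, cy, bw, bh = it.boxes[0]
        x1, y1 = int((cx - bw / 2) * w), int((cy - bh / 2) * h)
        x2, y2 = int((cx + bw / 2) * w), int((cy + bh / 2) * h)
        crop = it.image[max(y1, 0):y2, max(x1, 0):x2]
        small = np.asarray(Image.fromarray(crop).resize((16, 16))).astype(np.float32)
        small -= small.mean()  # brightness-normalised
        return small.ravel() / (np.linalg.norm(small) + 1e-9)

    by_class = {}
    for it in fixture_dataset.items:
        by_class.setdefault(it.boxes[0][0], []).append(signature(it))
    intra, inter = [], []
    classes = sorted(by_class)
    for c in classes:
        sig = np.stack(by_class[c])
        d = np.linalg.norm(sig[:, None] - sig[None], axis=-1)
        intra.append(d[np.triu_indices(len(sig), 1)].mean())
        for c2 in classes:
            if c2 > c:
                sig2 = np.stack(by_class[c2])
                inter.append(np.linalg.norm(sig[:, None] - sig2[None],
                                            axis=-1).mean())
    assert np.mean(inter) > np.mean(intra)


def test_label_io_roundtrip(tmp_path):
    boxes = [(0, 0.5, 0.5, 0.25, 0.3), (2, 0.4, 0.6, 0.1, 0.2)]
    p = tmp_path / "x.txt"
    write_labels(p, boxes)
    got = read_labels(p)
    assert [b[0] for b in got] == [0, 2]
    np.testing.assert_allclose(np.array(got)[:, 1:], np.array(boxes)[:, 1:],
                               atol=1e-6)


@pytest.fixture()
def rng():
    return np.random.default_rng(17)
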