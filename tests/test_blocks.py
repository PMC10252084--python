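"""Block-level contracts: channel split/shuffle algebra, ghost-module
compression, ShuffleNetv2 units, SPPF pooling equivalence and the
attention gates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sheepface import blocks as B
from sheepface.autograd import Tensor
from sheepface.blocks import (C3, C3Ghost, CBAM, Conv, CoordAtt, ECA,
                              GhostBottleneck, GhostConv, ProfileAccumulator,
                              SPPF, ShuffleUnit, SqueezeExcite, channel_shuffle,
                              channel_split, ghost_flops_ratio, make_attention)


def feat(c, h, w, rng=None, const=None):
    if const is not None:
        return Tensor(np.full((1, c, h, w), const, dtype=np.float32))
    rng = rng or np.random.default_rng(0)
    return Tensor(rng.normal(0, 1, (1, c, h, w)).astype(np.float32))


def params_of(mod):
    return sum(p.data.size for p in mod.parameters())


# ------------------------------------------------------------ split/shuffle --

def test_channel_split_halves_and_concat_recovers():
    x = feat(4, 3, 3)
    a, b = channel_split(x)
    assert a.shape[1] == b.shape[1] == 2
    np.testing.assert_array_equal(a.data, x.data[:, :2])
    np.testing.assert_array_equal(b.data, x.data[:, 2:])
    np.testing.assert_array_equal(Tensor.concat([a, b], axis=1).data, x.data)


def test_channel_split_rejects_odd_channels():
    with pytest.raises(ValueError):
        channel_split(feat(3, 2, 2))


def test_channel_shuffle_permutation():
    # channels labelled 0..3: reshape(2, 2) + transpose gives [0, 2, 1, 3]
    x = Tensor(np.arange(4, dtype=np.float32).reshape(1, 4, 1, 1))
    y = channel_shuffle(x, 2)
    assert y.data[0, :, 0, 0].tolist() == [0.0, 2.0, 1.0, 3.0]
    # groups=1 is the identity; shuffling twice with g=2 on 4 channels too
    np.testing.assert_array_equal(channel_shuffle(x, 1).data, x.data)
    np.testing.assert_array_equal(channel_shuffle(y, 2).data, x.data)


@given(g=st.integers(1, 8), mult=st.integers(1, 6))
@settings(max_examples=30, deadline=None)
def test_channel_shuffle_is_bijective(g, mult):
    c = g * mult
    x = Tensor(np.arange(c, dtype=np.float32).reshape(1, c, 1, 1))
    y = channel_shuffle(x, g)
    assert sorted(y.data[0, :, 0, 0].tolist()) == list(range(c))


def test_channel_shuffle_rejects_non_divisible():
    with pytest.raises(ValueError):
        channel_shuffle(feat(5, 1, 1), 2)


# ------------------------------------------------------------- shuffle unit --

def test_shuffle_unit_shapes():
    rng = np.random.default_rng(2)
    u1 = ShuffleUnit(64, 64, s=1, rng=rng)
    assert u1(feat(64, 32, 32)).shape == (1, 64, 32, 32)
    u2 = ShuffleUnit(64, 128, s=2, rng=rng)
    assert u2(feat(64, 32, 32)).shape == (1, 128, 16, 16)


def test_shuffle_unit_stride1_rejects_channel_change():
    with pytest.raises(ValueError):
        ShuffleUnit(64, 128, s=1)


@pytest.mark.parametrize("ci,co", [(32, 64), (64, 128), (128, 256), (256, 512)])
def test_shuffle_downsample_parameter_closed_form(ci, co):
    # hand-summed per-layer terms: left DW3(ci)+BN + 1x1(ci->co/2)+BN;
    # right 1x1(ci->co/2)+BN + DW3(co/2)+BN + 1x1(co/2->co/2)+BN
    half = co // 2
    expected = (9 * ci + 2 * ci) + (ci * half + 2 * half) \
        + (ci * half + 2 * half) + (9 * half + 2 * half) \
        + (half * half + 2 * half)
    unit = ShuffleUnit(ci, co, s=2)
    assert params_of(unit) == expected
    acc = ProfileAccumulator()
    unit.profile((ci, 8, 8), acc)
    assert acc.total_params == expected


# -------------------------------------------------------------------- ghost --

def test_ghost_conv_channel_budget_and_s1_limit():
    g = GhostConv(16, 64)   # default ratio 2: 32 primary + 32 cheap
    y = g(feat(16, 8, 8))
    assert y.shape == (1, 64, 8, 8)
    assert g.cv1.c2 == 32 and g.cv2.c1 == 32
    # s=1 degenerates to an ordinary convolution, no cheap branch
    g1 = GhostConv(16, 64, ratio=1)
    assert g1.cv2 is None and g1(feat(16, 8, 8)).shape == (1, 64, 8, 8)
    with pytest.raises(ValueError):
        GhostConv(16, 63)


def test_ghost_conv_parameter_closed_form():
    c, n, k, d = 16, 64, 1, 5
    m = n // 2
    expected = c * m * k * k + 2 * m + (n - m) * d * d + 2 * (n - m)
    assert params_of(GhostConv(c, n, k)) == expected


def test_ghost_flops_ratio_examples_and_bounds():
    assert ghost_flops_ratio(c=240, k=3, d=3, s=1) == pytest.approx(1.0)
    # hand-evaluated: 2160 / (1080 + 4.5)
    assert ghost_flops_ratio(c=240, k=3, d=3, s=2) == pytest.approx(2160 / 1084.5)
    with pytest.raises(ValueError):
        ghost_flops_ratio(c=0, k=3, d=3, s=2)


@given(c=st.integers(1, 4096), s=st.integers(1, 8))
@settings(max_examples=60, deadline=None)
def test_ghost_flops_ratio_in_unit_interval_and_increasing(c, s):
    r = ghost_flops_ratio(c, 3, 3, s)
    assert 1.0 <= r <= s + 1e-9
    if c > 1:
        assert r >= ghost_flops_ratio(c - 1, 3, 3, s) - 1e-12


def test_ghost_flops_ratio_approaches_s():
    assert ghost_flops_ratio(10 ** 7, 3, 3, 4) == pytest.approx(4.0, rel=1e-4)


def test_ghost_bottleneck_shapes_and_residual_identity():
    gb = GhostBottleneck(64, 64, s=1)
    x = feat(64, 16, 16)
    assert gb(x).shape == (1, 64, 16, 16)
    gb2 = GhostBottleneck(64, 128, s=2)
    assert gb2(feat(64, 16, 16)).shape == (1, 128, 8, 8)
    # zeroing the second ghost module makes the block the identity (the
    # stride-1 shortcut is a pass-through)
    gb.eval()
    for conv in (gb.g2.cv1, gb.g2.cv2):
        conv.weight.data[...] = 0.0
        conv.gamma.data[...] = 0.0
        conv.beta.data[...] = 0.0
    np.testing.assert_allclose(gb(x).data, x.data, atol=1e-6)


def test_c3ghost_contract():
    x = feat(128, 8, 8)
    cg = C3Ghost(128, 128, n=1)
    assert cg(x).shape == x.shape
    # strictly fewer parameters than the plain C3 at the same config
    assert params_of(cg) < params_of(C3(128, 128, n=1))
    # n=1 is a single ghost bottleneck inside the split/fuse convs
    assert len(cg.m) == 1 and isinstance(cg.m[0], GhostBottleneck)


@given(c=st.sampled_from([32, 64, 128, 256]), s=st.integers(2, 4))
@settings(max_examples=20, deadline=None)
def test_ghost_cheaper_than_dense_conv(c, s):
    if c % s:
        return
    dense = Conv(c, c, 3)
    ghost = GhostConv(c, c, 3, ratio=s)
    assert params_of(ghost) < params_of(dense)


# --------------------------------------------------------------------- sppf --

def brute_force_spp(x: np.ndarray, ks=(5, 9, 13)) -> list[np.ndarray]:
    """Reference parallel SPP pooling via explicit window maxima."""
    outs = []
    for k in ks:
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        h, w = x.shape[2:]
        out = np.empty_like(x)
        for i in range(h):
            for j in range(w):
                out[:, :, i, j] = xp[:, :, i:i + k, j:j + k].max(axis=(2, 3))
        outs.append(out)
    return outs


def test_sppf_chained_pools_equal_parallel_spp(rng):
    x = rng.normal(0, 1, (1, 3, 9, 9)).astype(np.float32)
    t = Tensor(x)
    y1 = t.maxpool2d(5)
    y2 = y1.maxpool2d(5)
    y3 = y2.maxpool2d(5)
    for got, want in zip((y1, y2, y3), brute_force_spp(x)):
        np.testing.assert_allclose(got.data, want)


def test_sppf_shape_and_constant_invariance():
    sp = SPPF(64, 64)
    sp.eval()
    assert sp(feat(64, 12, 12)).shape == (1, 64, 12, 12)
    xc = feat(64, 6, 6, const=2.5)
    y0 = sp.cv1(xc)
    np.testing.assert_allclose(y0.maxpool2d(5).data, y0.data, atol=1e-6)


# ---------------------------------------------------------------- attention --

@pytest.mark.parametrize("kind", ["ca", "se", "eca", "cbam"])
def test_attention_preserves_shape_and_gates_bounded(kind):
    rng = np.random.default_rng(5)
    att = make_attention(kind, 32, rng=rng)
    att.eval()
    x = feat(32, 6, 7, rng)
    y = att(x)
    assert y.shape == x.shape
    # reweighting only: |y| <= |x| elementwise since every gate is in (0,1)
    assert np.all(np.abs(y.data) <= np.abs(x.data) + 1e-6)


def test_unknown_attention_kind_rejected():
    with pytest.raises(ValueError):
        make_attention("simam", 32)


def test_se_symmetric_channels_get_identical_weights():
    # with channel-symmetric MLP weights, identical input channels must
    # receive identical gates (and each gate is spatially constant)
    rng = np.random.default_rng(6)
    se = SqueezeExcite(8, rng=rng)
    se.fc1.weight.data[...] = 0.3
    se.fc1.bias.data[...] = 0.1
    se.fc2.weight.data[...] = -0.2
    se.fc2.bias.data[...] = 0.05
    base = rng.normal(0, 1, (1, 1, 5, 5)).astype(np.float32)
    x = Tensor(np.repeat(base, 8, axis=1))
    w = se(x).data / x.data
    assert np.allclose(w.min(axis=(0, 2, 3)), w.max(axis=(0, 2, 3)), atol=1e-6)
    assert np.ptp(w.mean(axis=(2, 3))) < 1e-6  # identical across channels
    assert np.all((w > 0) & (w < 1))


def test_coordatt_constant_input_pools_to_constant():
    ca = CoordAtt(4, width=4)
    x = feat(4, 3, 5, const=1.7)
    zh = x.mean(axis=3, keepdims=True)
    zw = x.mean(axis=2, keepdims=True)
    assert np.allclose(zh.data, 1.7) and np.allclose(zw.data, 1.7)
    ca.eval()
    assert ca(x).shape == x.shape


def test_coordatt_hand_oracle_single_channel():
    """1-channel 2x2 map, identity convs, identity nonlinearity: the output
    must equal x[i,j] * sigmoid(row_mean_i) * sigmoid(col_mean_j)."""
    ca = CoordAtt(1, width=1)
    ca.eval()
    ca.conv1.weight.data[...] = 1.0
    ca.conv1.bias.data[...] = 0.0
    ca.conv1.has_bn = False
    ca.conv1._act = lambda t: t          # delta = identity for the oracle
    for gate in (ca.conv_h, ca.conv_w):
        gate.weight.data[...] = 1.0
        gate.bias.data[...] = 0.0
    x = np.array([[1.0, 2.0], [3.0, 4.0]], dtype=np.float32)
    got = ca(Tensor(x[None, None])).data[0, 0]
    sig = lambda v: 1 / (1 + np.exp(-v))
    gh = sig(x.mean(axis=1))             # per-row gate
    gw = sig(x.mean(axis=0))             # per-column gate
    expected = x * gh[:, None] * gw[None, :]
    np.testing.assert_allclose(got, expected, rtol=1e-5)


def test_coordatt_weights_strictly_in_unit_interval(rng):
    ca = CoordAtt(8, width=4)
    ca.eval()
    gh, gw = ca.attention_weights(feat(8, 5, 6, rng))
    assert gh.shape == (8, 5) and gw.shape == (8, 6)
    for g in (gh, gw):
        assert np.all(g > 0) and np.all(g < 1)


def test_calibrated_coordatt_parameter_budget():
    # the attention-slot block reproduces the published +293,936 delta
    att = make_attention("ca", 512, calibrated=True)
    assert params_of(att) == 293_936


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
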