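"""Building blocks for the lightweight sheep-face detector.

The vocabulary follows the YOLOv5 family: ``Conv`` is the CBS unit
(convolution + batch norm + SiLU), ``C3`` the cross-stage-partial block,
``SPPF`` the fast spatial-pyramid-pooling block.  The lightweight
substitutions are ghost convolution (`GhostConv`, `GhostBottleneck`,
`C3Ghost`) and the ShuffleNetv2 units, plus four attention gates
(coordinate attention, squeeze-excitation, efficient channel attention,
CBAM) that can be slotted in front of SPPF.

All blocks are shape-deterministic: output dimensions are a pure function
of the input dimensions and the block configuration, which is what the
analytic profiler relies on (every block implements ``profile``).
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module", "Conv", "DWConv", "Bottleneck", "C3", "SPPF",
    "GhostConv", "GhostBottleneck", "C3Ghost",
    "ShuffleUnit", "channel_split", "channel_shuffle", "ghost_flops_ratio",
    "CoordAtt", "SqueezeExcite", "ECA", "CBAM", "make_attention",
    "ProfileAccumulator",
]


class ProfileAccumulator:
    """Collects per-layer analytic parameter and MAC counts.

    The FLOPs reporting convention (documented in the profiler module)
    additionally needs the number of batch-normalised output elements, so
    primitives record those too.
    """

    def __init__(self):
        self.rows: list[tuple[str, int, int]] = []  # (name, params, macs)
        self.bn_elements = 0

    def add(self, name: str, params: int, macs: int):
        self.rows.append((name, int(params), int(macs)))

    @property
    def total_params(self) -> int:
        return sum(r[1] for r in self.rows)

    @property
    def total_macs(self) -> int:
        return sum(r[2] for r in self.rows)


class Module:
    """Tiny nn.Module analogue: parameter traversal + train/eval mode."""

    training = True

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def children(self) -> Iterator["Module"]:
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def modules(self) -> Iterator["Module"]:
        yield self
        for c in self.children():
            yield from c.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor) and v.requires_grad:
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")

    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, np.ndarray):
                yield name, v
            elif isinstance(v, Module):
                yield from v.buffers(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.buffers(f"{name}.{i}.")

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def profile(self, shape: tuple[int, int, int], acc: ProfileAccumulator,
                name: str = "") -> tuple[int, int, int]:
        """Propagate (C, H, W) through the block, accumulating params/MACs."""
        raise NotImplementedError(type(self).__name__)


def _init_conv_weight(shape, rng: np.random.Generator) -> Tensor:
    fan_in = int(np.prod(shape[1:]))
    bound = 1.0 / math.sqrt(fan_in)
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


def autopad(k: int) -> int:
    return k // 2


_ACTS = {
    "silu": Tensor.silu,
    "relu": Tensor.relu,
    "hswish": Tensor.hardswish,
    "sigmoid": Tensor.sigmoid,
    "identity": lambda t: t,
}


class Conv(Module):
    """CBS unit: Conv2d (no bias) + BatchNorm + activation (SiLU default)."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1,
                 p: int | None = None, g: int = 1, act: str | bool = "silu",
                 rng: np.random.Generator | None = None,
                 bias: bool = False, bn: bool = True):
        rng = rng or np.random.default_rng(0)
        if g not in (1, c1):
            raise ValueError("only dense (g=1) or depthwise (g=c1) convs supported")
        dw = g == c1 and g != 1
        if dw and c2 != c1:
            raise ValueError("depthwise conv requires c1 == c2")
        self.c1, self.c2, self.k, self.s = c1, c2, k, s
        self.g = c1 if dw else 1
        self.is_dw = dw
        self.p = autopad(k) if p is None else p
        wshape = (c2, 1, k, k) if dw else (c2, c1, k, k)
        self.weight = _init_conv_weight(wshape, rng)
        self.bias = Tensor(np.zeros(c2), requires_grad=True) if bias else None
        self.has_bn = bn
        if bn:
            self.gamma = Tensor(np.ones(c2), requires_grad=True)
            self.beta = Tensor(np.zeros(c2), requires_grad=True)
            self.running_mean = np.zeros(c2, dtype=np.float32)
            self.running_var = np.ones(c2, dtype=np.float32)
        if act is True:
            act = "silu"
        elif act is False or act is None:
            act = "identity"
        self.act_name = act
        self._act = _ACTS[act]

    def forward(self, x: Tensor) -> Tensor:
        if self.is_dw:
            y = x.dwconv2d(self.weight, stride=self.s, padding=self.p)
        else:
            y = x.conv2d(self.weight, self.bias, stride=self.s, padding=self.p)
        if self.has_bn:
            y = y.batchnorm(self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training)
        return self._act(y)

    # analytic accounting ------------------------------------------------
    def param_count(self) -> int:
        n = self.k * self.k * (1 if self.is_dw else self.c1) * self.c2
        if self.bias is not None:
            n += self.c2
        if self.has_bn:
            n += 2 * self.c2
        return n

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        oh = (h + 2 * self.p - self.k) // self.s + 1
        ow = (w + 2 * self.p - self.k) // self.s + 1
        return oh, ow

    def profile(self, shape, acc, name="conv"):
        c, h, w = shape
        if c != self.c1:
            raise ValueError(f"{name}: expected {self.c1} channels, got {c}")
        oh, ow = self.out_hw(h, w)
        kk = self.k * self.k * (1 if self.is_dw else self.c1)
        macs = kk * self.c2 * oh * ow
        acc.add(name, self.param_count(), macs)
        if self.has_bn:
            acc.bn_elements += self.c2 * oh * ow
        return (self.c2, oh, ow)


def DWConv(c: int, k: int = 3, s: int = 1, act: str | bool = "silu",
           rng=None) -> Conv:
    """Depthwise convolution with BN (one filter per channel)."""
    return Conv(c, c, k, s, g=c, act=act, rng=rng)


class Bottleneck(Module):
    """Standard residual bottleneck used inside C3 (1x1 then 3x3 conv)."""

    def __init__(self, c1, c2, shortcut=True, e=0.5, rng=None):
        c_ = int(c2 * e)
        self.cv1 = Conv(c1, c_, 1, rng=rng)
        self.cv2 = Conv(c_, c2, 3, rng=rng)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y

    def profile(self, shape, acc, name="bneck"):
        s = self.cv1.profile(shape, acc, f"{name}.cv1")
        s = self.cv2.profile(s, acc, f"{name}.cv2")
        return s


class C3(Module):
    """Cross-stage-partial block: split, bottleneck stack, concat, fuse."""

    def __init__(self, c1, c2, n=1, shortcut=True, e=0.5, rng=None):
        c_ = int(c2 * e)
        self.cv1 = Conv(c1, c_, 1, rng=rng)
        self.cv2 = Conv(c1, c_, 1, rng=rng)
        self.cv3 = Conv(2 * c_, c2, 1, rng=rng)
        self.m = [Bottleneck(c_, c_, shortcut, e=1.0, rng=rng) for _ in range(n)]

    def forward(self, x):
        y1 = self.cv1(x)
        for b in self.m:
            y1 = b(y1)
        y2 = self.cv2(x)
        return self.cv3(Tensor.concat([y1, y2], axis=1))

    def profile(self, shape, acc, name="c3"):
        s1 = self.cv1.profile(shape, acc, f"{name}.cv1")
        for i, b in enumerate(self.m):
            s1 = b.profile(s1, acc, f"{name}.m{i}")
        s2 = self.cv2.profile(shape, acc, f"{name}.cv2")
        return self.cv3.profile((s1[0] + s2[0], s1[1], s1[2]), acc, f"{name}.cv3")


class SPPF(Module):
    """Spatial pyramid pooling (fast): three chained 5x5 stride-1 max pools.

    Equivalent to parallel 5/9/13 pooling of the classic SPP block because a
    composition of stride-1 max filters widens the effective window.
    """

    def __init__(self, c1, c2, k=5, rng=None):
        c_ = c1 // 2
        self.cv1 = Conv(c1, c_, 1, rng=rng)
        self.cv2 = Conv(c_ * 4, c2, 1, rng=rng)
        self.k = k

    def forward(self, x):
        y0 = self.cv1(x)
        y1 = y0.maxpool2d(self.k)
        y2 = y1.maxpool2d(self.k)
        y3 = y2.maxpool2d(self.k)
        return self.cv2(Tensor.concat([y0, y1, y2, y3], axis=1))

    def profile(self, shape, acc, name="sppf"):
        s = self.cv1.profile(shape, acc, f"{name}.cv1")
        return self.cv2.profile((4 * s[0], s[1], s[2]), acc, f"{name}.cv2")


# ------------------------------------------------------------------ ghost ---

def ghost_flops_ratio(c: int, k: int, d: int, s: int) -> float:
    """Speed-up of ordinary convolution over the ghost module.

    Exact value of the compression ratio before the ~s approximation:
    (c*k^2) / (c*k^2/s + d^2*(s-1)/s).  Tends to s as c grows with k=d
    fixed, and equals 1 when s=1 (no cheap branch).
    """
    if c <= 0 or k <= 0 or d <= 0 or s < 1:
        raise ValueError("c, k, d must be positive and s >= 1")
    denom = c * k * k / s + d * d * (s - 1) / s
    if denom == 0:
        raise ZeroDivisionError("degenerate ghost configuration")
    return (c * k * k) / denom


class GhostConv(Module):
    """Ghost convolution: half the outputs from an ordinary convolution,
    half from cheap 5x5 depthwise ops on those primary maps."""

    def __init__(self, c1, c2, k=1, s=1, act: str | bool = "silu",
                 ratio: int = 2, dw_kernel: int = 5, rng=None):
        if c2 % ratio:
            raise ValueError(f"out_channels {c2} not divisible by ghost ratio {ratio}")
        self.ratio = ratio
        c_ = c2 // ratio
        self.cv1 = Conv(c1, c_, k, s, act=act, rng=rng)
        # cheap branch: depthwise linear ops; absent in the s=1 limit
        self.cv2 = None if ratio == 1 else Conv(c_, c_, dw_kernel, 1, g=c_,
                                                act=act, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        if self.cv2 is None:
            return y
        return Tensor.concat([y, self.cv2(y)], axis=1)

    def profile(self, shape, acc, name="ghost"):
        s = self.cv1.profile(shape, acc, f"{name}.cv1")
        if self.cv2 is None:
            return s
        s2 = self.cv2.profile(s, acc, f"{name}.cv2")
        return (s[0] + s2[0], s2[1], s2[2])


class GhostBottleneck(Module):
    """Two stacked ghost modules; a stride-2 depthwise conv between them
    (and on the shortcut) in the downsampling form."""

    def __init__(self, c1, c2, k=3, s=1, rng=None):
        if s not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        c_ = c2 // 2
        self.s = s
        self.g1 = GhostConv(c1, c_, 1, 1, rng=rng)
        self.dw = DWConv(c_, k, s, act=False, rng=rng) if s == 2 else None
        self.g2 = GhostConv(c_, c2, 1, 1, act=False, rng=rng)
        if s == 2:
            self.sc_dw = DWConv(c1, k, s, act=False, rng=rng)
            self.sc_pw = Conv(c1, c2, 1, 1, act=False, rng=rng)
        else:
            if c1 != c2:
                raise ValueError("stride-1 ghost bottleneck needs c1 == c2 "
                                 "for the residual add")
            self.sc_dw = self.sc_pw = None

    def forward(self, x):
        y = self.g1(x)
        if self.dw is not None:
            y = self.dw(y)
        y = self.g2(y)
        sc = x if self.sc_dw is None else self.sc_pw(self.sc_dw(x))
        if y.shape != sc.shape:
            raise ValueError(f"residual shape mismatch {y.shape} vs {sc.shape}")
        return y + sc

    def profile(self, shape, acc, name="gbneck"):
        s = self.g1.profile(shape, acc, f"{name}.g1")
        if self.dw is not None:
            s = self.dw.profile(s, acc, f"{name}.dw")
        s = self.g2.profile(s, acc, f"{name}.g2")
        if self.sc_dw is not None:
            sc = self.sc_dw.profile(shape, acc, f"{name}.sc_dw")
            self.sc_pw.profile(sc, acc, f"{name}.sc_pw")
        return s


class C3Ghost(C3):
    """C3 block with ghost bottlenecks as the repeated unit."""

    def __init__(self, c1, c2, n=1, shortcut=True, e=0.5, rng=None):
        super().__init__(c1, c2, n, shortcut, e, rng=rng)
        c_ = int(c2 * e)
        self.m = [GhostBottleneck(c_, c_, rng=rng) for _ in range(n)]


# ------------------------------------------------------------- shufflenet ---

def channel_split(x: Tensor) -> tuple[Tensor, Tensor]:
    """Split a feature map into two halves along the channel axis."""
    c = x.shape[1]
    if c % 2:
        raise ValueError(f"channel_split requires even channel count, got {c}")
    return x.narrow(1, 0, c // 2), x.narrow(1, c // 2, c // 2)


def channel_shuffle(x: Tensor, groups: int) -> Tensor:
    """Interleave channels across groups: reshape C->(g, C/g), transpose,
    flatten.  A pure permutation of channel indices."""
    n, c, h, w = x.shape
    if c % groups:
        raise ValueError(f"channels {c} not divisible by groups {groups}")
    return (x.reshape(n, groups, c // groups, h, w)
             .transpose(0, 2, 1, 3, 4)
             .reshape(n, c, h, w))


class ShuffleUnit(Module):
    """ShuffleNetv2 unit.

    stride 1: channel split; the right branch runs 1x1 conv, 3x3 depthwise,
    1x1 conv; concat; channel shuffle.  Requires c1 == c2 (even).
    stride 2: both branches downsample (left: 3x3 DW s2 + 1x1; right:
    1x1 + 3x3 DW s2 + 1x1), concat to c2, channel shuffle.

    Following the original design, 1x1 convolutions are followed by BN+ReLU
    and depthwise convolutions by BN only.
    """

    def __init__(self, c1: int, c2: int, s: int = 1, rng=None):
        if s not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        self.s = s
        self.c1, self.c2 = c1, c2
        c_ = c2 // 2
        if s == 1:
            if c1 != c2:
                raise ValueError("stride-1 shuffle unit requires c1 == c2")
            if c1 % 2:
                raise ValueError("stride-1 shuffle unit requires even channels")
            self.r1 = Conv(c_, c_, 1, act="relu", rng=rng)
            self.r2 = DWConv(c_, 3, 1, act=False, rng=rng)
            self.r3 = Conv(c_, c_, 1, act="relu", rng=rng)
        else:
            self.l1 = DWConv(c1, 3, 2, act=False, rng=rng)
            self.l2 = Conv(c1, c_, 1, act="relu", rng=rng)
            self.r1 = Conv(c1, c_, 1, act="relu", rng=rng)
            self.r2 = DWConv(c_, 3, 2, act=False, rng=rng)
            self.r3 = Conv(c_, c_, 1, act="relu", rng=rng)

    def forward(self, x):
        if self.s == 1:
            left, right = channel_split(x)
            right = self.r3(self.r2(self.r1(right)))
        else:
            left = self.l2(self.l1(x))
            right = self.r3(self.r2(self.r1(x)))
        return channel_shuffle(Tensor.concat([left, right], axis=1), 2)

    def profile(self, shape, acc, name="shuffle"):
        c, h, w = shape
        if self.s == 1:
            half = (c // 2, h, w)
            s = self.r1.profile(half, acc, f"{name}.r1")
            s = self.r2.profile(s, acc, f"{name}.r2")
            s = self.r3.profile(s, acc, f"{name}.r3")
            return (c, h, w)
        sl = self.l1.profile(shape, acc, f"{name}.l1")
        sl = self.l2.profile(sl, acc, f"{name}.l2")
        sr = self.r1.profile(shape, acc, f"{name}.r1")
        sr = self.r2.profile(sr, acc, f"{name}.r2")
        sr = self.r3.profile(sr, acc, f"{name}.r3")
        return (sl[0] + sr[0], sr[1], sr[2])


# -------------------------------------------------------------- attention ---

class SqueezeExcite(Module):
    """Channel gate: global average pool, bottleneck MLP, sigmoid weights."""

    def __init__(self, c: int, reduction: int = 16, width: int | None = None,
                 rng=None):
        mid = width if width is not None else max(1, c // reduction)
        self.fc1 = Conv(c, mid, 1, act="relu", bias=True, bn=False, rng=rng)
        self.fc2 = Conv(mid, c, 1, act="sigmoid", bias=True, bn=False, rng=rng)

    def forward(self, x):
        z = x.mean(axis=(2, 3), keepdims=True)
        return x * self.fc2(self.fc1(z))

    def profile(self, shape, acc, name="se"):
        c, h, w = shape
        self.fc1.profile((c, 1, 1), acc, f"{name}.fc1")
        self.fc2.profile((self.fc1.c2, 1, 1), acc, f"{name}.fc2")
        return shape


class ECA(Module):
    """Efficient channel attention: 1-D conv over the channel descriptor."""

    def __init__(self, c: int, k: int = None, rng=None):
        if k is None:
            # adaptive kernel of the ECA formulation: odd, ~log2(C)/2 + 1/2
            t = int(abs(math.log2(c) / 2 + 0.5))
            k = t if t % 2 else t + 1
            k = max(k, 3)
        rng = rng or np.random.default_rng(0)
        self.k = k
        self.c = c
        self.weight = Tensor(rng.uniform(-1, 1, size=k) / math.sqrt(k),
                             requires_grad=True)

    def forward(self, x):
        n, c = x.shape[0], x.shape[1]
        z = x.mean(axis=(2, 3), keepdims=True).reshape(n, c)
        pad = self.k // 2
        zp = Tensor.concat([Tensor(np.zeros((n, pad), dtype=np.float32)), z,
                            Tensor(np.zeros((n, pad), dtype=np.float32))], axis=1)
        # 1-D conv along the channel axis as a sum of shifted slices
        w = None
        for j in range(self.k):
            term = zp.narrow(1, j, c) * self.weight.narrow(0, j, 1)
            w = term if w is None else w + term
        return x * w.reshape(n, c, 1, 1).sigmoid()

    def profile(self, shape, acc, name="eca"):
        acc.add(name, self.k, self.k * self.c)
        return shape


class CBAM(Module):
    """Convolutional block attention: channel gate (avg+max shared MLP)
    then a 7x7 spatial gate."""

    def __init__(self, c: int, reduction: int = 16, spatial_k: int = 7, rng=None):
        mid = max(1, c // reduction)
        self.fc1 = Conv(c, mid, 1, act="relu", bias=True, bn=False, rng=rng)
        self.fc2 = Conv(mid, c, 1, act="identity", bias=True, bn=False, rng=rng)
        self.spatial = Conv(2, 1, spatial_k, act="identity", bias=True, bn=False,
                            rng=rng)

    def forward(self, x):
        avg = x.mean(axis=(2, 3), keepdims=True)
        mx = _spatial_max(x)
        cg = (self.fc2(self.fc1(avg)) + self.fc2(self.fc1(mx))).sigmoid()
        x = x * cg
        savg = x.mean(axis=1, keepdims=True)
        smax = _channel_max(x)
        sg = self.spatial(Tensor.concat([savg, smax], axis=1)).sigmoid()
        return x * sg

    def profile(self, shape, acc, name="cbam"):
        c, h, w = shape
        self.fc1.profile((c, 1, 1), acc, f"{name}.fc1")
        self.fc2.profile((self.fc1.c2, 1, 1), acc, f"{name}.fc2")
        self.spatial.profile((2, h, w), acc, f"{name}.spatial")
        return shape


def _spatial_max(x: Tensor) -> Tensor:
    """Max over (H, W) with gradient routed to the argmax positions."""
    n, c, h, w = x.shape
    flat = x.reshape(n, c, h * w)
    arg = flat.data.argmax(axis=2)
    idx = (np.arange(n)[:, None], np.arange(c)[None, :], arg)
    return flat[idx].reshape(n, c, 1, 1)


def _channel_max(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    arg = x.data.argmax(axis=1)
    nn_, hh, ww = np.meshgrid(np.arange(n), np.arange(h), np.arange(w),
                              indexing="ij")
    return x[(nn_, arg, hh, ww)].reshape(n, 1, h, w)


class CoordAtt(Module):
    """Coordinate attention: directional pooling -> shared bottleneck ->
    per-row and per-column sigmoid gates multiplied back onto the input.

    ``width`` fixes the bottleneck width directly; otherwise it is
    ``max(8, c // reduction)``.  ``se_width`` adds an auxiliary
    squeeze-excitation channel gate (the block then provides both spatial
    and channel attention); the calibrated profile uses
    ``width=184, gate_bn=True, gate_bias=False, se_width=8`` at C=512 —
    see docs/methods.md for how that calibration was fixed.
    """

    def __init__(self, c: int, reduction: int = 32, width: int | None = None,
                 gate_bias: bool = True, gate_bn: bool = False,
                 se_width: int | None = None, rng=None):
        mid = width if width is not None else max(8, c // reduction)
        if mid < 1:
            raise ValueError("coordinate-attention bottleneck collapsed to zero width")
        self.c, self.mid = c, mid
        self.conv1 = Conv(c, mid, 1, act="hswish", bias=True, bn=True, rng=rng)
        self.conv_h = Conv(mid, c, 1, act="identity", bias=gate_bias, bn=gate_bn,
                           rng=rng)
        self.conv_w = Conv(mid, c, 1, act="identity", bias=gate_bias, bn=gate_bn,
                           rng=rng)
        self.se = SqueezeExcite(c, width=se_width, rng=rng) if se_width else None

    def forward(self, x):
        n, c, h, w = x.shape
        zh = x.mean(axis=3, keepdims=True)                      # (n, c, h, 1)
        zw = x.mean(axis=2, keepdims=True).transpose(0, 1, 3, 2)  # (n, c, w, 1)
        f = self.conv1(Tensor.concat([zh, zw], axis=2))
        fh = f.narrow(2, 0, h)
        fw = f.narrow(2, h, w)
        gh = self.conv_h(fh).sigmoid()                           # (n, c, h, 1)
        gw = self.conv_w(fw).sigmoid().transpose(0, 1, 3, 2)     # (n, c, 1, w)
        y = x * gh * gw
        if self.se is not None:
            y = self.se(y)
        return y

    def attention_weights(self, x: Tensor) -> tuple[np.ndarray, np.ndarray]:
        """Return (g_h: C x H, g_w: C x W) gates for a single image."""
        n, c, h, w = x.shape
        zh = x.mean(axis=3, keepdims=True)
        zw = x.mean(axis=2, keepdims=True).transpose(0, 1, 3, 2)
        f = self.conv1(Tensor.concat([zh, zw], axis=2))
        gh = self.conv_h(f.narrow(2, 0, h)).sigmoid()
        gw = self.conv_w(f.narrow(2, h, w)).sigmoid()
        return gh.data[0, :, :, 0], gw.data[0, :, :, 0]

    def profile(self, shape, acc, name="ca"):
        c, h, w = shape
        self.conv1.profile((c, h + w, 1), acc, f"{name}.conv1")
        self.conv_h.profile((self.mid, h, 1), acc, f"{name}.conv_h")
        self.conv_w.profile((self.mid, w, 1), acc, f"{name}.conv_w")
        if self.se is not None:
            self.se.profile(shape, acc, f"{name}.se")
        return shape


def make_attention(kind: str, c: int, rng=None, calibrated: bool = True) -> Module:
    """Factory for the attention slot in front of SPPF.

    ``kind`` is one of {"ca", "se", "eca", "cbam"}.  For "ca" the
    calibrated profile (bottleneck 184 + channel gate 8 at C=512) is the
    default; pass ``calibrated=False`` for the textbook reduction-32 block.
    """
    kind = kind.lower()
    if kind == "ca":
        if calibrated:
            return CoordAtt(c, width=184, gate_bias=False, gate_bn=True,
                            se_width=8, rng=rng)
        return CoordAtt(c, rng=rng)
    if kind == "se":
        return SqueezeExcite(c, rng=rng)
    if kind == "eca":
        return ECA(c, rng=rng)
    if kind == "cbam":
        return CBAM(c, rng=rng)
    raise ValueError(f"unknown attention kind: {kind!r}")
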