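"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the detector needs: dense and depthwise
2-D convolution (via im2col and BLAS matmul), batch normalisation with
running statistics, the usual pointwise nonlinearities, stride-1 max
pooling, nearest-neighbour upsampling, concatenation/splitting, reshapes,
fancy-index gathers and the elementwise arithmetic used by the loss.

Design notes
------------
* ``Tensor`` wraps a float32 ndarray.  Gradients are accumulated in
  ``.grad`` during :meth:`Tensor.backward`, which walks a topologically
  sorted tape.
* Convolution lowers to ``im2col`` + a single matmul per layer; the
  backward pass reuses the stored column matrix.  ``col2im`` scatters with
  one slice-add per kernel tap (k*k slice ops, no np.add.at in the hot
  path).
* Everything is float32 end to end; parameters keep velocity buffers for
  SGD with momentum outside this module.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _as_f32(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float32)
    return a


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs are ~hundreds of nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free interior grads/tape as we go to bound memory
                node._backward = None
                node._parents = ()

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
        if g.shape == shape:
            return g
        extra = g.ndim - len(shape)
        if extra:
            g = g.sum(axis=tuple(range(extra)))
        axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
        if axes:
            g = g.sum(axis=axes, keepdims=True)
        return g

    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        o = self._coerce(other)

        def bw(g):
            if self.requires_grad:
                self._accum(self._unbroadcast(g, self.data.shape))
            if o.requires_grad:
                o._accum(self._unbroadcast(g, o.data.shape))

        return Tensor._make(self.data + o.data, (self, o), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        o = self._coerce(other)

        def bw(g):
            if self.requires_grad:
                self._accum(self._unbroadcast(g * o.data, self.data.shape))
            if o.requires_grad:
                o._accum(self._unbroadcast(g * self.data, o.data.shape))

        return Tensor._make(self.data * o.data, (self, o), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._coerce(other)

        def bw(g):
            if self.requires_grad:
                self._accum(self._unbroadcast(g / o.data, self.data.shape))
            if o.requires_grad:
                o._accum(self._unbroadcast(-g * self.data / (o.data * o.data), o.data.shape))

        return Tensor._make(self.data / o.data, (self, o), bw)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        def bw(g):
            self._accum(g * p * np.power(self.data, p - 1))

        return Tensor._make(np.power(self.data, p), (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accum(g * 0.5 / np.maximum(out_data, 1e-12))

        return Tensor._make(out_data, (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def arctan(self):
        def bw(g):
            self._accum(g / (1.0 + self.data * self.data))

        return Tensor._make(np.arctan(self.data), (self,), bw)

    def clamp(self, lo=None, hi=None):
        mask = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            mask &= self.data >= lo
        if hi is not None:
            mask &= self.data <= hi

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), bw)

    def sum(self, axis=None, keepdims=False):
        def bw(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def maximum(self, other):
        o = self._coerce(other)
        choose_self = self.data >= o.data

        def bw(g):
            if self.requires_grad:
                self._accum(self._unbroadcast(g * choose_self, self.data.shape))
            if o.requires_grad:
                o._accum(self._unbroadcast(g * (~choose_self), o.data.shape))

        return Tensor._make(np.maximum(self.data, o.data), (self, o), bw)

    def minimum(self, other):
        o = self._coerce(other)
        choose_self = self.data <= o.data

        def bw(g):
            if self.requires_grad:
                self._accum(self._unbroadcast(g * choose_self, self.data.shape))
            if o.requires_grad:
                o._accum(self._unbroadcast(g * (~choose_self), o.data.shape))

        return Tensor._make(np.minimum(self.data, o.data), (self, o), bw)

    # --------------------------------------------------------- shape plumbing
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def bw(g):
            self._accum(g.reshape(orig))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(self.data[idx], (self,), bw)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = 1) -> "Tensor":
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bw(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(a, b)
                    t._accum(g[tuple(sl)])

        return Tensor._make(
            np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw
        )

    def narrow(self, axis: int, start: int, length: int) -> "Tensor":
        sl = [slice(None)] * self.data.ndim
        sl[axis] = slice(start, start + length)
        sl = tuple(sl)

        def bw(g):
            full = np.zeros_like(self.data)
            full[sl] = g
            self._accum(full)

        return Tensor._make(self.data[sl], (self,), bw)

    # ---------------------------------------------------------- nonlinearity
    def sigmoid(self):
        with np.errstate(over="ignore"):   # exp overflow saturates to 0/1
            s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * s * (1.0 - s))

        return Tensor._make(s, (self,), bw)

    def silu(self):
        with np.errstate(over="ignore"):
            s = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * s

        def bw(g):
            self._accum(g * (s + out_data * (1.0 - s)))

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def hardswish(self):
        x = self.data
        inner = np.clip(x + 3.0, 0.0, 6.0)

        def bw(g):
            d = np.where(x <= -3.0, 0.0, np.where(x >= 3.0, 1.0, (2.0 * x + 3.0) / 6.0))
            self._accum(g * d.astype(np.float32))

        return Tensor._make(x * inner / 6.0, (self,), bw)

    # ------------------------------------------------------------ convolution
    @staticmethod
    def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
        if p == 0:
            return x
        return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))

    @staticmethod
    def _im2col(xp: np.ndarray, k: int, s: int, oh: int, ow: int) -> np.ndarray:
        """(N, C, Hp, Wp) -> (N, C*k*k, oh*ow) via one strided slice per tap."""
        n, c, _, _ = xp.shape
        cols = np.empty((n, c, k * k, oh * ow), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                patch = xp[:, :, i : i + s * oh : s, j : j + s * ow : s]
                cols[:, :, i * k + j, :] = patch.reshape(n, c, -1)
        return cols.reshape(n, c * k * k, oh * ow)

    @staticmethod
    def _col2im(gcols: np.ndarray, xshape, k: int, s: int, p: int, oh: int, ow: int) -> np.ndarray:
        n, c, h, w = xshape
        gx = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        gc = gcols.reshape(n, c, k * k, oh, ow)
        for i in range(k):
            for j in range(k):
                gx[:, :, i : i + s * oh : s, j : j + s * ow : s] += gc[:, :, i * k + j]
        if p:
            gx = gx[:, :, p:-p, p:-p]
        return gx

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0) -> "Tensor":
        """Dense 2-D convolution. weight: (Cout, Cin, k, k)."""
        x = self.data
        n, cin, h, w = x.shape
        cout, cin_w, k, _ = weight.data.shape
        if cin_w != cin:
            raise ValueError(f"conv2d: input has {cin} channels, weight expects {cin_w}")
        oh = (h + 2 * padding - k) // stride + 1
        ow = (w + 2 * padding - k) // stride + 1
        xp = self._pad_hw(x, padding)
        cols = self._im2col(xp, k, stride, oh, ow)  # (N, cin*k*k, L)
        wmat = weight.data.reshape(cout, -1)
        out = np.einsum("ol,nlp->nop", wmat, cols, optimize=True)
        out = np.ascontiguousarray(out).reshape(n, cout, oh, ow)
        if bias is not None:
            out += bias.data.reshape(1, cout, 1, 1)

        parents = (self, weight) if bias is None else (self, weight, bias)

        def bw(g):
            gmat = g.reshape(n, cout, -1)  # (N, cout, L)
            if weight.requires_grad:
                gw = np.einsum("nop,nlp->ol", gmat, cols, optimize=True)
                weight._accum(gw.reshape(weight.data.shape))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                gcols = np.einsum("ol,nop->nlp", wmat, gmat, optimize=True)
                self._accum(self._col2im(gcols, x.shape, k, stride, padding, oh, ow))

        return Tensor._make(out, parents, bw)

    def dwconv2d(self, weight: "Tensor", stride: int = 1, padding: int = 0) -> "Tensor":
        """Depthwise convolution. weight: (C, 1, k, k), one filter per channel."""
        x = self.data
        n, c, h, w = x.shape
        cw, _, k, _ = weight.data.shape
        if cw != c:
            raise ValueError("dwconv2d: channel mismatch")
        oh = (h + 2 * padding - k) // stride + 1
        ow = (w + 2 * padding - k) // stride + 1
        xp = self._pad_hw(x, padding)
        cols = self._im2col(xp, k, stride, oh, ow).reshape(n, c, k * k, oh * ow)
        wmat = weight.data.reshape(c, k * k)
        out = np.einsum("nckp,ck->ncp", cols, wmat, optimize=True).reshape(n, c, oh, ow)

        def bw(g):
            gmat = g.reshape(n, c, -1)
            if weight.requires_grad:
                gw = np.einsum("ncp,nckp->ck", gmat, cols, optimize=True)
                weight._accum(gw.reshape(weight.data.shape))
            if self.requires_grad:
                gcols = np.einsum("ncp,ck->nckp", gmat, wmat, optimize=True)
                gcols = gcols.reshape(n, c * k * k, oh * ow)
                self._accum(self._col2im(gcols, x.shape, k, stride, padding, oh, ow))

        return Tensor._make(out, (self, weight), bw)

    # -------------------------------------------------------- pooling/resize
    def maxpool2d(self, k: int, stride: int = 1, padding: int | None = None) -> "Tensor":
        if padding is None:
            padding = k // 2
        x = self.data
        n, c, h, w = x.shape
        oh = (h + 2 * padding - k) // stride + 1
        ow = (w + 2 * padding - k) // stride + 1
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
        cols = self._im2col(xp.astype(np.float32), k, stride, oh, ow)
        cols = cols.reshape(n, c, k * k, oh * ow)
        arg = cols.argmax(axis=2)
        out = np.take_along_axis(cols, arg[:, :, None, :], axis=2)[:, :, 0, :]

        def bw(g):
            gcols = np.zeros((n, c, k * k, oh * ow), dtype=np.float32)
            np.put_along_axis(gcols, arg[:, :, None, :], g.reshape(n, c, 1, -1), axis=2)
            gx = self._col2im(gcols.reshape(n, c * k * k, -1), x.shape, k, stride,
                              padding, oh, ow)
            self._accum(gx)

        return Tensor._make(out.reshape(n, c, oh, ow), (self,), bw)

    def upsample2x(self) -> "Tensor":
        x = self.data
        out = x.repeat(2, axis=2).repeat(2, axis=3)

        def bw(g):
            n, c, h2, w2 = g.shape
            gr = g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
            self._accum(gr)

        return Tensor._make(out, (self,), bw)

    # ------------------------------------------------------------- batchnorm
    def batchnorm(self, gamma: "Tensor", beta: "Tensor", running_mean: np.ndarray,
                  running_var: np.ndarray, training: bool, momentum: float = 0.03,
                  eps: float = 1e-3) -> "Tensor":
        """Channel-wise batch normalisation over (N, H, W).

        Running statistics are updated in place when ``training``.
        """
        x = self.data
        if training:
            axes = (0, 2, 3)
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            nhw = x.shape[0] * x.shape[2] * x.shape[3]
            running_mean *= 1.0 - momentum
            running_mean += momentum * mu
            unbiased = var * (nhw / max(nhw - 1, 1))
            running_var *= 1.0 - momentum
            running_var += momentum * unbiased
        else:
            mu = running_mean
            var = running_var
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
        out = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)

        def bw(g):
            axes = (0, 2, 3)
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta._accum(g.sum(axis=axes))
            if self.requires_grad:
                gx_hat = g * gamma.data.reshape(1, -1, 1, 1)
                if training:
                    nhw = x.shape[0] * x.shape[2] * x.shape[3]
                    mean_g = gx_hat.mean(axis=axes, keepdims=True)
                    mean_gx = (gx_hat * xhat).mean(axis=axes, keepdims=True)
                    gx = (gx_hat - mean_g - xhat * mean_gx) * inv.reshape(1, -1, 1, 1)
                else:
                    gx = gx_hat * inv.reshape(1, -1, 1, 1)
                self._accum(gx.astype(np.float32))

        return Tensor._make(out.astype(np.float32), (self, gamma, beta), bw)

    # ------------------------------------------------------------------ loss
    def bce_with_logits(self, target: np.ndarray, reduction: str = "mean") -> "Tensor":
        """Numerically stable binary cross-entropy on logits."""
        x = self.data
        t = np.asarray(target, dtype=np.float32)
        loss = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))
        if reduction == "mean":
            out_data = np.float32(loss.mean())
        elif reduction == "sum":
            out_data = np.float32(loss.sum())
        else:
            raise ValueError(reduction)

        def bw(g):
            with np.errstate(over="ignore"):
                s = 1.0 / (1.0 + np.exp(-x))
            gx = (s - t) * g
            if reduction == "mean":
                gx = gx / loss.size
            self._accum(gx.astype(np.float32))

        return Tensor._make(out_data, (self,), bw)
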