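"""Reverse-mode automatic differentiation on numpy arrays.

A minimal define-by-run tape: every operation returns a new :class:`Tensor`
holding its value, its parents, and a closure that accumulates gradients into
the parents. Convolutions use im2col views (``sliding_window_view``) so the
heavy lifting stays inside BLAS einsums. All tensors are float64 — the
networks in this package run at desk scale, where the accuracy of gradient
checks matters more than raw throughput.

Layout convention for feature maps: ``(N, C, H, W, D)`` — batch, channels,
rows, columns, slices.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` to undo numpy broadcasting."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data.item())

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _acc(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        """Backpropagate from this (typically scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._acc(_unbroadcast(g, self.shape))
            other._acc(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._acc(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._acc(_unbroadcast(g * other.data, self.shape))
            other._acc(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._acc(_unbroadcast(g / other.data, self.shape))
            other._acc(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return self._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        def bw(g):
            self._acc(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), bw)

    def __matmul__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._acc(g @ other.data.T)
            other._acc(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bw)

    # -- elementwise nonlinearities --------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._acc(g * out_data)

        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._acc(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._acc(g * 0.5 / out_data)

        return self._make(out_data, (self,), bw)

    def abs(self):
        def bw(g):
            self._acc(g * np.sign(self.data))

        return self._make(np.abs(self.data), (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._acc(g * mask)

        return self._make(self.data * mask, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bw(g):
            self._acc(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bw)

    def swish(self):
        """x * sigmoid(x)."""
        return self * self.sigmoid()

    def clip(self, lo: float | None, hi: float | None):
        """Clamp values; gradient passes only through unclipped entries."""
        mask = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            mask &= self.data >= lo
        if hi is not None:
            mask &= self.data <= hi

        def bw(g):
            self._acc(g * mask)

        return self._make(np.clip(self.data, lo, hi), (self,), bw)

    # -- reductions and shape ops ----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if axis is None:
                self._acc(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._acc(np.broadcast_to(g, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(g):
            self._acc(g.reshape(self.shape))

        return self._make(self.data.reshape(shape), (self,), bw)

    def flatten(self):
        return self.reshape(-1)

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._acc(full)

        return self._make(self.data[idx], (self,), bw)

    def take_flat(self, indices: np.ndarray):
        """Gather from the flattened tensor; backward scatter-adds."""
        indices = np.asarray(indices)
        flat = self.data.reshape(-1)

        def bw(g):
            full = np.zeros(self.size)
            np.add.at(full, indices, g)
            self._acc(full.reshape(self.shape))

        return self._make(flat[indices], (self,), bw)

    def pad_spatial(self, pads):
        """Zero-pad the three trailing spatial axes of an (N,C,H,W,D) map.

        ``pads`` is ((h0,h1),(w0,w1),(d0,d1)).
        """
        width = [(0, 0), (0, 0), *pads]
        (h0, h1), (w0, w1), (d0, d1) = pads
        H, W, D = self.shape[2:]

        def bw(g):
            self._acc(g[:, :, h0 : h0 + H, w0 : w0 + W, d0 : d0 + D])

        return self._make(np.pad(self.data, width), (self,), bw)

    def crop_spatial(self, shape):
        """Center-crop the three trailing spatial axes to ``shape``."""
        H, W, D = self.shape[2:]
        th, tw, td = shape
        o = ((H - th) // 2, (W - tw) // 2, (D - td) // 2)
        sl = (
            slice(None),
            slice(None),
            slice(o[0], o[0] + th),
            slice(o[1], o[1] + tw),
            slice(o[2], o[2] + td),
        )

        def bw(g):
            full = np.zeros_like(self.data)
            full[sl] = g
            self._acc(full)

        return self._make(self.data[sl], (self,), bw)

    def upsample_nearest(self, factors):
        """Nearest-neighbour upsampling of the spatial axes by integer factors."""
        fh, fw, fd = factors
        out_data = self.data.repeat(fh, axis=2).repeat(fw, axis=3).repeat(fd, axis=4)
        N, C, H, W, D = self.shape

        def bw(g):
            g = g.reshape(N, C, H, fh, W, fw, D, fd).sum(axis=(3, 5, 7))
            self._acc(g)

        return self._make(out_data, (self,), bw)

    # -- convolutions -----------------------------------------------------
    def conv3d(self, weight: "Tensor", bias: "Tensor | None" = None, stride=(1, 1, 1)):
        """'same'-padded 3D convolution.

        ``weight`` has shape (out_ch, in_ch, kh, kw, kd). Output spatial size
        is ``ceil(in / stride)`` per axis (padding split evenly, extra at the
        end). Kernels of size 1 along an axis convolve slice-wise, so 2D
        slice-by-slice networks are expressed with (k, k, 1) kernels.
        """
        return _conv3d(self, weight, bias, stride, depthwise=False)

    def depthwise_conv3d(self, weight: "Tensor", bias: "Tensor | None" = None, stride=(1, 1, 1)):
        """Per-channel ('depthwise') 3D convolution; weight (C, kh, kw, kd)."""
        return _conv3d(self, weight, bias, stride, depthwise=True)

    def conv_transpose3d(self, weight: "Tensor", bias: "Tensor | None" = None, stride=(2, 2, 2)):
        """Transposed convolution with kernel equal to stride (exact adjoint
        of a non-overlapping strided convolution): each input voxel paints a
        (sh, sw, sd) block in the output.

        ``weight`` has shape (in_ch, out_ch, sh, sw, sd).
        """
        N, C, H, W, D = self.shape
        Ci, O, sh, sw, sd = weight.shape
        if Ci != C:
            raise ValueError(f"channel mismatch: input {C}, weight {Ci}")
        out_data = np.einsum("ncxyz,coijk->noxiyjzk", self.data, weight.data, optimize=True)
        out_data = out_data.reshape(N, O, H * sh, W * sw, D * sd)
        if bias is not None:
            out_data = out_data + bias.data.reshape(1, O, 1, 1, 1)

        def bw(g):
            gb = g.reshape(N, O, H, sh, W, sw, D, sd)
            self._acc(np.einsum("noxiyjzk,coijk->ncxyz", gb, weight.data, optimize=True))
            weight._acc(np.einsum("noxiyjzk,ncxyz->coijk", gb, self.data, optimize=True))
            if bias is not None:
                bias._acc(g.sum(axis=(0, 2, 3, 4)))

        parents = (self, weight) if bias is None else (self, weight, bias)
        return self._make(out_data, parents, bw)


def _same_pads(size: int, k: int, s: int) -> tuple[int, int]:
    out = -(-size // s)  # ceil
    total = max((out - 1) * s + k - size, 0)
    return total // 2, total - total // 2


def _conv3d(x: Tensor, weight: Tensor, bias, stride, depthwise: bool) -> Tensor:
    N, C, H, W, D = x.shape
    if depthwise:
        Cw, kh, kw, kd = weight.shape
        if Cw != C:
            raise ValueError(f"channel mismatch: input {C}, depthwise weight {Cw}")
        O = C
    else:
        O, Ci, kh, kw, kd = weight.shape
        if Ci != C:
            raise ValueError(f"channel mismatch: input {C}, weight {Ci}")
    sh, sw, sd = stride
    pads = (_same_pads(H, kh, sh), _same_pads(W, kw, sw), _same_pads(D, kd, sd))
    xp = np.pad(x.data, [(0, 0), (0, 0), *pads])
    win = sliding_window_view(xp, (kh, kw, kd), axis=(2, 3, 4))
    win = win[:, :, ::sh, ::sw, ::sd]  # (N, C, Ho, Wo, Do, kh, kw, kd)
    if depthwise:
        out_data = np.einsum("ncxyzijk,cijk->ncxyz", win, weight.data, optimize=True)
    else:
        out_data = np.einsum("ncxyzijk,ocijk->noxyz", win, weight.data, optimize=True)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, O, 1, 1, 1)
    Ho, Wo, Do = out_data.shape[2:]

    def bw(g):
        if depthwise:
            weight._acc(np.einsum("ncxyzijk,ncxyz->cijk", win, g, optimize=True))
        else:
            weight._acc(np.einsum("ncxyzijk,noxyz->ocijk", win, g, optimize=True))
        if bias is not None:
            bias._acc(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    for k in range(kd):
                        if depthwise:
                            patch = g * weight.data[None, :, i, j, k, None, None, None]
                        else:
                            patch = np.einsum(
                                "noxyz,oc->ncxyz", g, weight.data[:, :, i, j, k], optimize=True
                            )
                        gxp[
                            :,
                            :,
                            i : i + Ho * sh : sh,
                            j : j + Wo * sw : sw,
                            k : k + Do * sd : sd,
                        ] += patch
            x._acc(gxp[:, :, pads[0][0] : pads[0][0] + H, pads[1][0] : pads[1][0] + W, pads[2][0] : pads[2][0] + D])

    parents = (x, weight) if bias is None else (x, weight, bias)
    return x._make(out_data, parents, bw)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis``."""
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._acc(g[tuple(sl)])

    out = Tensor(data, requires_grad=any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = bw
    return out
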