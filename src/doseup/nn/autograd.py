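"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical engine behind the translation networks: a small,
deterministic tape of array operations with hand-written vector-Jacobian
products. It supports exactly the operations the generator, PatchGAN
discriminator and patch-contrastive losses need (broadcast arithmetic,
matmul, 2-D convolution, pooling, padding, patch gathering and the usual
pointwise nonlinearities). Everything runs on the CPU.

Gradients accumulate into ``Tensor.grad`` as plain ndarrays. Graphs are
built eagerly and freed after ``backward`` unless retained by the caller.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free graph references as we go
            node._backward = None
            node._parents = ()

    # -- construction helper ---------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: tuple, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other, like=self)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            a._accumulate(-g)

        return Tensor._make(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other, like=self))

    def __rsub__(self, other):
        return as_tensor(other, like=self) + (-self)

    def __mul__(self, other):
        other = as_tensor(other, like=self)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other, like=self)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return Tensor._make(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return as_tensor(other, like=self) / self

    def __pow__(self, p: float):
        a = self

        def bw(g):
            a._accumulate(g * p * np.power(a.data, p - 1))

        return Tensor._make(np.power(a.data, p), (a,), bw)

    def __matmul__(self, other):
        other = as_tensor(other, like=self)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.data.shape))

        return Tensor._make(a.data @ b.data, (a, b), bw)

    # -- pointwise nonlinearities ----------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            a._accumulate(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bw)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bw(g):
            a._accumulate(g * 0.5 / out_data)

        return Tensor._make(out_data, (a,), bw)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bw(g):
            a._accumulate(g * (1.0 - out_data ** 2))

        return Tensor._make(out_data, (a,), bw)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def bw(g):
            a._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), bw)

    def relu(self):
        a = self
        mask = a.data > 0

        def bw(g):
            a._accumulate(g * mask)

        return Tensor._make(a.data * mask, (a,), bw)

    def leaky_relu(self, slope: float = 0.2):
        a = self
        mask = a.data > 0
        scale = np.where(mask, 1.0, slope).astype(a.data.dtype, copy=False)

        def bw(g):
            a._accumulate(g * scale)

        return Tensor._make(a.data * scale, (a,), bw)

    def abs(self):
        a = self
        sign = np.sign(a.data)

        def bw(g):
            a._accumulate(g * sign)

        return Tensor._make(np.abs(a.data), (a,), bw)

    # -- reductions & shaping --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bw(g):
            if axis is None:
                ga = np.broadcast_to(g, a.data.shape)
            else:
                ga = g if keepdims else np.expand_dims(g, axis)
                ga = np.broadcast_to(ga, a.data.shape)
            a._accumulate(ga.astype(a.data.dtype, copy=False))

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(g):
            a._accumulate(g.reshape(a.data.shape))

        return Tensor._make(a.data.reshape(shape), (a,), bw)

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            a._accumulate(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), bw)

    # -- image ops (NCHW) -------------------------------------------------
    def pad2d(self, pad: int, mode: str = "zero"):
        """Pad the last two axes by ``pad`` on each side (zero/reflect/edge)."""
        a = self
        if pad == 0:
            return self
        np_mode = {"zero": "constant", "reflect": "reflect", "edge": "edge"}[mode]
        width = [(0, 0)] * (a.ndim - 2) + [(pad, pad), (pad, pad)]
        out_data = np.pad(a.data, width, mode=np_mode)

        def bw(g):
            core = g[..., pad:-pad, pad:-pad].copy()
            if mode == "reflect":
                # fold reflected borders back onto their sources
                H, W = a.data.shape[-2:]
                gfull = np.zeros_like(a.data)
                gfull += core
                for i in range(pad):
                    gfull[..., pad - i, :] += g[..., i, pad:-pad]
                    gfull[..., H - 2 - i, :] += g[..., H + pad + i, pad:-pad]
                for j in range(pad):
                    gfull[..., :, pad - j] += g[..., pad:-pad, j]
                    gfull[..., :, W - 2 - j] += g[..., pad:-pad, W + pad + j]
                # corners reflect along both axes
                for i in range(pad):
                    for j in range(pad):
                        gfull[..., pad - i, pad - j] += g[..., i, j]
                        gfull[..., pad - i, W - 2 - j] += g[..., i, W + pad + j]
                        gfull[..., H - 2 - i, pad - j] += g[..., H + pad + i, j]
                        gfull[..., H - 2 - i, W - 2 - j] += g[..., H + pad + i, W + pad + j]
                a._accumulate(gfull)
            elif mode == "edge":
                gfull = core
                gfull[..., 0, :] += g[..., :pad, pad:-pad].sum(axis=-2)
                gfull[..., -1, :] += g[..., -pad:, pad:-pad].sum(axis=-2)
                gfull[..., :, 0] += g[..., pad:-pad, :pad].sum(axis=-1)
                gfull[..., :, -1] += g[..., pad:-pad, -pad:].sum(axis=-1)
                gfull[..., 0, 0] += g[..., :pad, :pad].sum(axis=(-1, -2))
                gfull[..., 0, -1] += g[..., :pad, -pad:].sum(axis=(-1, -2))
                gfull[..., -1, 0] += g[..., -pad:, :pad].sum(axis=(-1, -2))
                gfull[..., -1, -1] += g[..., -pad:, -pad:].sum(axis=(-1, -2))
                a._accumulate(gfull)
            else:
                a._accumulate(core)

        return Tensor._make(out_data, (a,), bw)

    def conv2d(self, weight: "Tensor", bias: "Tensor | None", stride: int = 1):
        """2-D cross-correlation, NCHW input, OIkk weight. No implicit padding.

        Decomposed over kernel offsets: each offset contributes one BLAS
        matmul on a cheap strided slice, avoiding large im2col gathers.
        """
        a, w = self, weight
        O, C, kh, kw = w.data.shape
        s = stride
        N, _, Hin, Win = a.data.shape
        Ho = (Hin - kh) // s + 1
        Wo = (Win - kw) // s + 1
        out_flat = np.zeros((N, O, Ho * Wo), dtype=a.data.dtype)
        # offset (i, j): out += W[:, :, i, j] @ x[:, :, i::s, j::s]
        for i in range(kh):
            for j in range(kw):
                sl = a.data[:, :, i: i + s * (Ho - 1) + 1: s,
                            j: j + s * (Wo - 1) + 1: s]
                out_flat += np.matmul(w.data[:, :, i, j],
                                      sl.reshape(N, C, Ho * Wo))
        if bias is not None:
            out_flat += bias.data[None, :, None]
        out_data = out_flat.reshape(N, O, Ho, Wo)
        parents = (a, w) if bias is None else (a, w, bias)

        def bw(g):
            gf = g.reshape(N, O, Ho * Wo)
            if bias is not None and bias.requires_grad:
                bias._accumulate(gf.sum(axis=(0, 2)))
            gw = np.empty((O, C, kh, kw), dtype=w.data.dtype) \
                if w.requires_grad else None
            ga = np.zeros_like(a.data) if a.requires_grad else None
            gT = np.ascontiguousarray(gf.transpose(0, 2, 1))  # (N, HW, O)
            for i in range(kh):
                for j in range(kw):
                    sl = a.data[:, :, i: i + s * (Ho - 1) + 1: s,
                                j: j + s * (Wo - 1) + 1: s]
                    if gw is not None:
                        # dW_ij = sum_n x_ij(n) @ g(n)^T
                        gw[:, :, i, j] = np.matmul(
                            sl.reshape(N, C, Ho * Wo), gT).sum(axis=0).T
                    if ga is not None:
                        # dx_ij += W_ij^T @ g
                        contrib = np.matmul(w.data[:, :, i, j].T, gf)
                        ga[:, :, i: i + s * (Ho - 1) + 1: s,
                           j: j + s * (Wo - 1) + 1: s] += contrib.reshape(
                            N, C, Ho, Wo)
            if gw is not None:
                w._accumulate(gw)
            if ga is not None:
                a._accumulate(ga)

        return Tensor._make(out_data, parents, bw)

    def upsample_nearest2x(self):
        a = self
        out_data = a.data.repeat(2, axis=-2).repeat(2, axis=-1)

        def bw(g):
            N, C, H2, W2 = g.shape
            ga = g.reshape(N, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))
            a._accumulate(ga)

        return Tensor._make(out_data, (a,), bw)

    def avg_pool2d(self, k: int = 2):
        a = self
        N, C, H, W = a.data.shape
        out_data = a.data.reshape(N, C, H // k, k, W // k, k).mean(axis=(3, 5))

        def bw(g):
            ga = np.repeat(np.repeat(g, k, axis=-2), k, axis=-1) / (k * k)
            a._accumulate(ga)

        return Tensor._make(out_data, (a,), bw)

    def fdiff(self, axis: int):
        """Forward difference along a spatial axis, replicate boundary.

        Output has the same shape; the trailing difference is zero (the
        boundary value is replicated).
        """
        a = self
        last = np.take(a.data, [-1], axis=axis)
        out_data = np.diff(a.data, axis=axis, append=last)

        def bw(g):
            ga = np.zeros_like(a.data)
            n = a.data.shape[axis]
            sl_lo = [slice(None)] * a.data.ndim
            sl_hi = [slice(None)] * a.data.ndim
            sl_g = [slice(None)] * a.data.ndim
            sl_lo[axis] = slice(0, n - 1)
            sl_hi[axis] = slice(1, n)
            sl_g[axis] = slice(0, n - 1)
            gv = g[tuple(sl_g)]
            ga[tuple(sl_hi)] += gv
            ga[tuple(sl_lo)] -= gv
            a._accumulate(ga)

        return Tensor._make(out_data, (a,), bw)

    def take_spatial(self, ids: np.ndarray):
        """Gather flattened spatial positions: (N,C,H,W) -> (N, K, C)."""
        a = self
        N, C, H, W = a.data.shape
        flat = a.data.reshape(N, C, H * W)
        out_data = flat[:, :, ids].transpose(0, 2, 1)

        def bw(g):
            gf = np.zeros((N, C, H * W), dtype=a.data.dtype)
            np.add.at(gf, (slice(None), slice(None), ids), g.transpose(0, 2, 1))
            a._accumulate(gf.reshape(a.data.shape))

        return Tensor._make(out_data, (a,), bw)


def as_tensor(x, like: Tensor | None = None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    dtype = like.data.dtype if like is not None else None
    return Tensor(np.asarray(x, dtype=dtype))
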