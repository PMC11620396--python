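"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operator set the package's networks and losses need:
elementwise arithmetic, reductions, leaky-rectifier / sigmoid / relu,
channel concatenation, 3D convolution (im2col, routed through BLAS
matmul), stride-2 transposed convolution, and instance normalization.
Tensors are float32 throughout; gradients are accumulated along a
topologically sorted tape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv3d", "conv_transpose3d", "instance_norm"]


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False):
        arr = np.asarray(data)
        # float64 inputs keep their precision (useful for gradient checks);
        # everything else becomes float32
        self.data = arr if arr.dtype == np.float64 else arr.astype(np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- autograd ------------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(node):
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    order.append(n)
                    continue
                if id(n) in seen or not n.requires_grad:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    stack.append((p, False))

        visit(self)
        self.grad = np.asarray(grad, self.data.dtype)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad):
        if not self.requires_grad:
            return
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=False)
        else:
            self.grad = self.grad + grad

    def _accum_slice(self, grad, ijk):
        # accumulate a conv-kernel slice gradient into grad[:, :, i, j, k]
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        i, j, k = ijk
        self.grad[:, :, i, j, k] += grad

    def zero_grad(self):
        self.grad = None

    # -- ops -----------------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data + other.data, (self, other), None)
        if out.requires_grad:
            def bw(g):
                self._accum(g)
                other._accum(g)
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._make(-self.data, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data * other.data, (self, other), None)
        if out.requires_grad:
            def bw(g):
                self._accum(g * other.data)
                other._accum(g * self.data)
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data / other.data, (self, other), None)
        if out.requires_grad:
            def bw(g):
                self._accum(g / other.data)
                other._accum(-g * self.data / other.data**2)
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def sum(self):
        out = Tensor._make(self.data.sum(keepdims=False), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(np.broadcast_to(g, self.data.shape))
        return out

    def mean(self):
        return self.sum() / float(self.data.size)

    def relu(self):
        mask = self.data > 0
        out = Tensor._make(self.data * mask, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * mask)
        return out

    def leaky_relu(self, slope=0.01):
        mask = self.data > 0
        out = Tensor._make(np.where(mask, self.data, slope * self.data), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * np.where(mask, 1.0, slope).astype(np.float32))
        return out

    def sigmoid(self):
        # numerically stable two-sided formulation
        x = self.data
        y = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                     np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        out = Tensor._make(y, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * y * (1 - y))
        return out

    def clip01(self, eps=0.0):
        y = np.clip(self.data, eps, 1 - eps)
        inside = (self.data > eps) & (self.data < 1 - eps)
        out = Tensor._make(y, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * inside)
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum a broadcast gradient back down to ``shape``."""
    g = np.asarray(grad)
    while g.ndim > len(shape):
        g = g.sum(0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(ax, keepdims=True)
    return g


def concat(tensors, axis=1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor._make(np.concatenate(datas, axis), tuple(tensors), None)
    if out.requires_grad:
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            for t, gi in zip(tensors, np.split(g, splits, axis)):
                t._accum(gi)

        out._backward = bw
    return out


# ---------------------------------------------------------------------------
# convolution


def conv3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """3D convolution with 'same' padding (pad = K//2).

    ``w`` has shape [O, C, K, K, K]. The kernel is unrolled into K³ offset
    slices, each contracted with a batched BLAS matmul — for the small
    channel counts of a desk-scale U-Net this moves far less memory than a
    full im2col gather.
    """
    O, C, K, _, _ = w.shape
    pad = K // 2
    N = x.shape[0]
    sp_in = x.shape[2:]
    out_sp = tuple((s + 2 * pad - K) // stride + 1 for s in sp_in)
    V = int(np.prod(out_sp))
    xp = np.pad(x.data, ((0, 0), (0, 0)) + ((pad, pad),) * 3)

    def slices(i, j, k):
        return (
            slice(None), slice(None),
            slice(i, i + stride * out_sp[0], stride),
            slice(j, j + stride * out_sp[1], stride),
            slice(k, k + stride * out_sp[2], stride),
        )

    y = np.zeros((N, O, V), np.float32)
    xslices = {}
    for i in range(K):
        for j in range(K):
            for k in range(K):
                xs = xp[slices(i, j, k)].reshape(N, C, V)
                xslices[i, j, k] = xs
                y += np.matmul(w.data[:, :, i, j, k], xs)
    y = y.reshape(N, O, *out_sp) + b.data.reshape(1, O, 1, 1, 1)
    out = Tensor._make(y, (x, w, b), None)
    if out.requires_grad:
        def bw(g):
            go = np.ascontiguousarray(g).reshape(N, O, V)
            if b.requires_grad:
                b._accum(go.sum((0, 2)))
            need_x = x.requires_grad
            gxp = np.zeros(xp.shape, np.float32) if need_x else None
            goT = go.transpose(0, 2, 1) if w.requires_grad else None  # (N, V, O)
            for i in range(K):
                for j in range(K):
                    for k in range(K):
                        if w.requires_grad:
                            xs = xslices[i, j, k]
                            gw = np.matmul(xs, goT).sum(0).T  # (O, C)
                            w._accum_slice(gw, (i, j, k))
                        if need_x:
                            gxs = np.matmul(w.data[:, :, i, j, k].T, go)
                            gxp[slices(i, j, k)] += gxs.reshape(N, C, *out_sp)
            if need_x:
                x._accum(gxp[:, :, pad:pad + sp_in[0], pad:pad + sp_in[1], pad:pad + sp_in[2]])
        out._backward = bw
    return out


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Transposed convolution with kernel 2, stride 2 (exact doubling).

    ``w`` has shape [C, O, 2, 2, 2]; output voxel (2d+i, 2h+j, 2w+k) gets
    sum_c x[c,d,h,w] * w[c,o,i,j,k] — windows do not overlap, so both the
    forward and backward pass are single tensor contractions.
    """
    C, O = w.shape[:2]
    N, _, D, H, W = x.shape
    xm = x.data.transpose(0, 2, 3, 4, 1).reshape(-1, C)  # (NV, C)
    wmat = w.data.reshape(C, -1)  # (C, O*8)
    y = (xm @ wmat).reshape(N, D, H, W, O, 2, 2, 2)
    y = y.transpose(0, 4, 1, 5, 2, 6, 3, 7).reshape(N, O, 2 * D, 2 * H, 2 * W)
    y = y + b.data.reshape(1, O, 1, 1, 1)
    out = Tensor._make(y, (x, w, b), None)
    if out.requires_grad:
        def bw(g):
            gr = g.reshape(N, O, D, 2, H, 2, W, 2).transpose(0, 2, 4, 6, 1, 3, 5, 7)
            gr = np.ascontiguousarray(gr).reshape(-1, O * 8)  # (NV, O8)
            if w.requires_grad:
                w._accum((xm.T @ gr).reshape(w.data.shape))
            if b.requires_grad:
                b._accum(g.sum((0, 2, 3, 4)))
            if x.requires_grad:
                gx = (gr @ wmat.T).reshape(N, D, H, W, C).transpose(0, 4, 1, 2, 3)
                x._accum(gx)
        out._backward = bw
    return out


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Instance normalization: zero mean / unit variance per sample and
    channel over the spatial axes, then per-channel affine."""
    axes = (2, 3, 4)
    mu = x.data.mean(axes, keepdims=True)
    var = x.data.var(axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gshape = (1, -1, 1, 1, 1)
    y = xhat * gamma.data.reshape(gshape) + beta.data.reshape(gshape)
    out = Tensor._make(y, (x, gamma, beta), None)
    if out.requires_grad:
        def bw(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum((0, 2, 3, 4)))
            if beta.requires_grad:
                beta._accum(g.sum((0, 2, 3, 4)))
            if x.requires_grad:
                gy = g * gamma.data.reshape(gshape)
                gx = inv * (
                    gy
                    - gy.mean(axes, keepdims=True)
                    - xhat * (gy * xhat).mean(axes, keepdims=True)
                )
                x._accum(gx.astype(np.float32))
        out._backward = bw
    return out
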