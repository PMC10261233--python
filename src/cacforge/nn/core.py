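"""Minimal reverse-mode autodiff on numpy arrays.

A deliberately small tape-based engine — just the operations the
package's convolutional networks need (dense/conv2d/conv3d layers,
pointwise nonlinearities, reductions). Everything is float32, seeded and
single-threaded numpy, which makes training runs bit-reproducible.
"""

from __future__ import annotations

import numpy as np


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev_state = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev_state
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph construction -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _child(self, data, prev, backward):
        out = Tensor(data, requires_grad=_GRAD_ENABLED and any(p.requires_grad for p in prev))
        if out.requires_grad:
            out._prev = tuple(prev)
            out._backward = backward
        return out

    def _accum(self, grad):
        if not self.requires_grad:
            return
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.astype(np.float32)
        else:
            self.grad = self.grad + grad

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            self._accum(g)
            other._accum(g)

        return self._child(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._child(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return self._child(out_data, (self, other), backward)

    __rmul__ = __mul__

    def square(self):
        def backward(g):
            self._accum(g * 2.0 * self.data)

        return self._child(self.data**2, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            self._accum(g * sign)

        return self._child(np.abs(self.data), (self,), backward)

    # -- reductions ----------------------------------------------------------

    def mean(self):
        n = self.data.size

        def backward(g):
            self._accum(np.full(self.data.shape, g / n, dtype=np.float32))

        return self._child(self.data.mean(), (self,), backward)

    def sum(self):
        def backward(g):
            self._accum(np.full(self.data.shape, g, dtype=np.float32))

        return self._child(self.data.sum(), (self,), backward)

    # -- nonlinearities -------------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return self._child(self.data * mask, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope).astype(np.float32)

        def backward(g):
            self._accum(g * factor)

        return self._child(self.data * factor, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -30, 30)))

        def backward(g):
            self._accum(g * s * (1.0 - s))

        return self._child(s, (self,), backward)

    def softplus(self):
        """log(1 + e^x): smooth, strictly positive, never gradient-dead."""
        z = np.clip(self.data, -30, 30)
        out = np.log1p(np.exp(z))
        sig = 1.0 / (1.0 + np.exp(-z))

        def backward(g):
            self._accum(g * sig)

        return self._child(out, (self,), backward)

    def log(self, eps: float = 1e-7):
        safe = np.maximum(self.data, eps)

        def backward(g):
            self._accum(g / safe)

        return self._child(np.log(safe), (self,), backward)

    # -- shape ops -------------------------------------------------------------

    def reshape(self, *shape):
        orig = self.data.shape

        def backward(g):
            self._accum(g.reshape(orig))

        return self._child(self.data.reshape(*shape), (self,), backward)

    def narrow(self, start: int, stop: int):
        """Slice along the batch (first) axis."""

        def backward(g):
            full = np.zeros_like(self.data)
            full[start:stop] = g
            self._accum(full)

        return self._child(self.data[start:stop], (self,), backward)

    def matmul(self, other: "Tensor"):
        """2-D @ 2-D matrix product."""
        other = _as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return self._child(out_data, (self, other), backward)

    # -- backprop ---------------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors, axis: int = 0) -> Tensor:
    """Concatenate tensors along an axis (with gradient splitting)."""
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    out = Tensor(out_data, requires_grad=_GRAD_ENABLED and any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum a gradient down to ``shape`` (inverse of numpy broadcasting)."""
    g = np.asarray(grad)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# Convolutions (im2col with stride support)
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """x: (N, C, H, W); w: (O, C, kh, kw); b: (O,). 'same'-style zero padding.

    Implemented as kernel-offset GEMMs on a channels-last copy, which is
    considerably faster in numpy than a full im2col materialization.
    """
    n, c, h, wd = x.data.shape
    o, c2, kh, kw = w.data.shape
    assert c == c2, (c, c2)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    ho = (xp.shape[2] - kh) // stride + 1
    wo = (xp.shape[3] - kw) // stride + 1
    xl = np.ascontiguousarray(xp.transpose(0, 2, 3, 1))  # (N, Hp, Wp, C)
    views = {}
    out = np.broadcast_to(b.data, (n, ho, wo, o)).copy()
    for i in range(kh):
        for j in range(kw):
            xv = xl[:, i : i + ho * stride : stride, j : j + wo * stride : stride, :].reshape(-1, c)
            views[i, j] = xv
            out += (xv @ w.data[:, :, i, j].T).reshape(n, ho, wo, o)

    def backward(g):
        gl = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, o)  # (N*Ho*Wo, O)
        if b.requires_grad:
            b._accum(gl.sum(axis=0))
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for (i, j), xv in views.items():
                dw[:, :, i, j] = gl.T @ xv
            w._accum(dw)
        if x.requires_grad:
            dxl = np.zeros_like(xl)
            for i in range(kh):
                for j in range(kw):
                    dxl[:, i : i + ho * stride : stride, j : j + wo * stride : stride, :] += (
                        gl @ w.data[:, :, i, j]
                    ).reshape(n, ho, wo, c)
            dxp = dxl.transpose(0, 3, 1, 2)
            x._accum(dxp[:, :, pad : pad + h, pad : pad + wd] if pad else dxp)

    return x._child(out.transpose(0, 3, 1, 2), (x, w, b), backward)


def conv3d(x: Tensor, w: Tensor, b: Tensor, pad: int = 0) -> Tensor:
    """x: (N, C, D, H, W); w: (O, C, kd, kh, kw); b: (O,). Stride 1 only.

    Same kernel-offset GEMM scheme as :func:`conv2d`.
    """
    n, c, d, h, wd = x.data.shape
    o, c2, kd, kh, kw = w.data.shape
    assert c == c2
    if pad:
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    else:
        xp = x.data
    do = xp.shape[2] - kd + 1
    ho = xp.shape[3] - kh + 1
    wo = xp.shape[4] - kw + 1
    xl = np.ascontiguousarray(xp.transpose(0, 2, 3, 4, 1))  # channels last
    views = {}
    out = np.broadcast_to(b.data, (n, do, ho, wo, o)).copy()
    for a in range(kd):
        for i in range(kh):
            for j in range(kw):
                xv = xl[:, a : a + do, i : i + ho, j : j + wo, :].reshape(-1, c)
                views[a, i, j] = xv
                out += (xv @ w.data[:, :, a, i, j].T).reshape(n, do, ho, wo, o)

    def backward(g):
        gl = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(-1, o)
        if b.requires_grad:
            b._accum(gl.sum(axis=0))
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for (a, i, j), xv in views.items():
                dw[:, :, a, i, j] = gl.T @ xv
            w._accum(dw)
        if x.requires_grad:
            dxl = np.zeros_like(xl)
            for a in range(kd):
                for i in range(kh):
                    for j in range(kw):
                        dxl[:, a : a + do, i : i + ho, j : j + wo, :] += (
                            gl @ w.data[:, :, a, i, j]
                        ).reshape(n, do, ho, wo, c)
            dxp = dxl.transpose(0, 4, 1, 2, 3)
            x._accum(dxp[:, :, pad : pad + d, pad : pad + h, pad : pad + wd] if pad else dxp)

    return x._child(out.transpose(0, 4, 1, 2, 3), (x, w, b), backward)


def global_max_pool(x: Tensor) -> Tensor:
    """(N, C, *spatial) -> (N, C): max over all spatial axes."""
    n, c = x.data.shape[:2]
    flat = x.data.reshape(n, c, -1)
    arg = flat.argmax(axis=2)
    out_data = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]

    def backward(g):
        gx = np.zeros_like(flat)
        np.put_along_axis(gx, arg[:, :, None], g[:, :, None], axis=2)
        x._accum(gx.reshape(x.data.shape))

    return x._child(out_data, (x,), backward)


def global_min_pool(x: Tensor) -> Tensor:
    """(N, C, *spatial) -> (N, C): min over all spatial axes."""
    return -global_max_pool(-x)


def global_mean_pool(x: Tensor) -> Tensor:
    """(N, C, *spatial) -> (N, C): mean over all spatial axes."""
    spatial_axes = tuple(range(2, x.data.ndim))
    n_spatial = int(np.prod([x.data.shape[a] for a in spatial_axes]))
    out_data = x.data.mean(axis=spatial_axes)

    def backward(g):
        g_full = (g / n_spatial).reshape(g.shape + (1,) * len(spatial_axes))
        x._accum(np.broadcast_to(g_full, x.data.shape).copy())

    return x._child(out_data, (x,), backward)
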