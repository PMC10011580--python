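"""Reverse-mode automatic differentiation over NumPy arrays.

A compact tape-based engine providing exactly the primitives needed by the
3D segmentation network: broadcasting arithmetic, matmul-free 3D convolution
(stride/padding), linear interpolation resampling, reductions, and the
pointwise nonlinearities.  Gradients are accumulated by topological traversal
of the recorded graph.  All floating point work is float32 unless the caller
supplies float64 (used by the finite-difference tests).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv3d", "linear_resize", "pad_zeros"]


class Tensor:
    """An array node in the autodiff graph.

    Parameters
    ----------
    data : array-like
        Wrapped value; copied to a contiguous ndarray.
    requires_grad : bool
        Whether gradients should be accumulated into ``.grad``.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self, grad=None):
        """Backpropagate from this node; seeds with ones for scalars."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
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
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                # free interior grads/graph as we go to bound memory
                if node is not self:
                    node.grad = None
                node._backward = None
                node._parents = ()

    # -- helpers -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    @staticmethod
    def _unbroadcast(g, shape):
        """Sum gradient ``g`` down to ``shape`` (inverse of broadcasting)."""
        extra = g.ndim - len(shape)
        if extra > 0:
            g = g.sum(axis=tuple(range(extra)))
        axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
        if axes:
            g = g.sum(axis=axes, keepdims=True)
        return g

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        if isinstance(other, (int, float)):  # scalar fast path, keeps dtype
            def backward_s(g):
                if self.requires_grad:
                    self._accum(g)

            return self._make(self.data + other, (self,), backward_s)
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(self._unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(self._unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return (-self) + other
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):  # scalar fast path, keeps dtype
            def backward_s(g):
                if self.requires_grad:
                    self._accum(g * other)

            return self._make(self.data * other, (self,), backward_s)
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(self._unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(self._unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(self._unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    self._unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(g):
            if self.requires_grad:
                self._accum(g * e * self.data ** (e - 1.0))

        return self._make(self.data**e, (self,), backward)

    # -- pointwise ---------------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)

        return self._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        mask = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions / shaping ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape))

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[idx] = g
                self._accum(full)

        return self._make(self.data[idx], (self,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis`` (channel dim by default)."""
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def pad_zeros(x: Tensor, pad) -> Tensor:
    """Zero-pad spatial axes of a (B, C, D, H, W) tensor.

    ``pad`` is ((d0,d1),(h0,h1),(w0,w1)).
    """
    widths = ((0, 0), (0, 0)) + tuple(pad)
    sl = tuple(slice(p0, x.shape[i] + p0) for i, (p0, _p1) in enumerate(widths))

    def backward(g):
        if x.requires_grad:
            x._accum(g[sl])

    return Tensor._make(np.pad(x.data, widths), (x,), backward)


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride=(1, 1, 1), padding=(0, 0, 0)) -> Tensor:
    """3D cross-correlation of (B,Cin,D,H,W) with (Cout,Cin,kd,kh,kw).

    Implemented as a sum over kernel offsets of strided tensor contractions,
    which avoids materialising an im2col buffer; the backward pass mirrors
    the same offset loop.
    """
    sd, sh, sw = stride
    kd, kh, kw = weight.shape[2:]
    pd, ph, pw = padding
    B, Cin, D, H, W = x.shape
    Dp, Hp, Wp = D + 2 * pd, H + 2 * ph, W + 2 * pw
    Do = (Dp - kd) // sd + 1
    Ho = (Hp - kh) // sh + 1
    Wo = (Wp - kw) // sw + 1
    Cout = weight.shape[0]
    wd = weight.data
    # channels-last working layout: offset-shifted views hit BLAS directly
    xcl = np.ascontiguousarray(x.data.transpose(0, 2, 3, 4, 1))
    if any(padding):
        xcl = np.pad(xcl, ((0, 0), (pd, pd), (ph, ph), (pw, pw), (0, 0)))
    out = np.zeros((B, Do, Ho, Wo, Cout), dtype=xcl.dtype)
    wcl = wd.transpose(2, 3, 4, 1, 0)  # (kd,kh,kw,Cin,Cout)
    for dz in range(kd):
        for dy in range(kh):
            for dx in range(kw):
                patch = xcl[:, dz:dz + sd * Do:sd, dy:dy + sh * Ho:sh,
                            dx:dx + sw * Wo:sw, :]
                out += patch @ wcl[dz, dy, dx].astype(xcl.dtype)
    if bias is not None:
        out += bias.data
    out = np.ascontiguousarray(out.transpose(0, 4, 1, 2, 3))

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gcl = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1))
        if bias is not None and bias.requires_grad:
            bias._accum(gcl.reshape(-1, Cout).sum(axis=0))
        gw = np.zeros_like(wd) if weight.requires_grad else None
        gxp = (np.zeros_like(xcl) if x.requires_grad else None)
        for dz in range(kd):
            for dy in range(kh):
                for dx in range(kw):
                    sl = (slice(None), slice(dz, dz + sd * Do, sd),
                          slice(dy, dy + sh * Ho, sh),
                          slice(dx, dx + sw * Wo, sw), slice(None))
                    if gw is not None:
                        gw[:, :, dz, dy, dx] = np.tensordot(
                            gcl, xcl[sl], axes=([0, 1, 2, 3], [0, 1, 2, 3]))
                    if gxp is not None:
                        gxp[sl] += gcl @ wcl[dz, dy, dx].T.astype(gcl.dtype)
        if gw is not None:
            weight._accum(gw)
        if gxp is not None:
            core = gxp[:, pd:pd + D, ph:ph + H, pw:pw + W, :]
            x._accum(np.ascontiguousarray(core.transpose(0, 4, 1, 2, 3)))

    return Tensor._make(out, parents, backward)


_RESIZE_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) linear-interpolation matrix, half-pixel centres."""
    key = (n_in, n_out)
    M = _RESIZE_CACHE.get(key)
    if M is None:
        pos = np.clip((np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5,
                      0, n_in - 1)
        i0 = np.floor(pos).astype(int)
        i1 = np.minimum(i0 + 1, n_in - 1)
        w1 = pos - i0
        M = np.zeros((n_out, n_in))
        M[np.arange(n_out), i0] += 1.0 - w1
        M[np.arange(n_out), i1] += w1
        _RESIZE_CACHE[key] = M
    return M


def linear_resize(x: Tensor, out_shape) -> Tensor:
    """Trilinear resize of the spatial axes of a (B,C,D,H,W) tensor.

    Separable: each axis is resized by multiplication with a small linear
    interpolation matrix, whose transpose gives the exact adjoint for the
    backward pass.
    """
    out = x
    for axis_offset, n_out in enumerate(out_shape):
        axis = 2 + axis_offset
        if out.shape[axis] != n_out:
            out = _linear_resize_axis(out, axis, n_out)
    return out


def _apply_matrix(arr: np.ndarray, M: np.ndarray, axis: int) -> np.ndarray:
    moved = np.moveaxis(arr, axis, -1)
    res = moved @ M.T.astype(arr.dtype)
    return np.ascontiguousarray(np.moveaxis(res, -1, axis))


def _linear_resize_axis(x: Tensor, axis: int, n_out: int) -> Tensor:
    M = _resize_matrix(x.shape[axis], n_out)

    def backward(g):
        if x.requires_grad:
            x._accum(_apply_matrix(g, M.T, axis))

    return Tensor._make(_apply_matrix(x.data, M, axis), (x,), backward)
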