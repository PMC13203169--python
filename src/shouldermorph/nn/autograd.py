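"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations needed by the volumetric networks in this
package: broadcast arithmetic, matmul, elementwise nonlinearities, axis
reductions, reshape/concat/slice, 3-D convolution (im2col via strided
windows), nearest-neighbour 2x upsampling and global average pooling.
Gradients are accumulated by topological-order backward passes; every op's
backward is verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv3d", "upsample2", "stack_params"]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- autograd plumbing ----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Run reverse-mode accumulation from this tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = _make(self.data + other.data, (self, other))

        def bw(g):
            _send(self, g)
            _send(other, g)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        out._backward = lambda g: _send(self, -g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _make(self.data * other.data, (self, other))

        def bw(g):
            _send(self, g * other.data)
            _send(other, g * self.data)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = _make(self.data / other.data, (self, other))

        def bw(g):
            _send(self, g / other.data)
            _send(other, -g * self.data / other.data**2)

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        out = _make(self.data**p, (self,))
        out._backward = lambda g: _send(self, g * p * self.data ** (p - 1))
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = _make(self.data @ other.data, (self, other))

        def bw(g):
            _send(self, g @ other.data.T)
            _send(other, self.data.T @ g)

        out._backward = bw
        return out

    __matmul__ = matmul

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = _make(self.data * mask, (self,))
        out._backward = lambda g: _send(self, g * mask)
        return out

    def exp(self):
        out = _make(np.exp(self.data), (self,))
        out._backward = lambda g: _send(self, g * out.data)
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        out._backward = lambda g: _send(self, g / self.data)
        return out

    def sigmoid(self):
        from scipy.special import expit

        s = expit(self.data)
        out = _make(s, (self,))
        out._backward = lambda g: _send(self, g * s * (1.0 - s))
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through the interior."""
        mask = (self.data > lo) & (self.data < hi)
        out = _make(np.clip(self.data, lo, hi), (self,))
        out._backward = lambda g: _send(self, g * mask)
        return out

    # -- reductions / shape ---------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            _send(self, np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = _make(self.data.reshape(*shape), (self,))
        out._backward = lambda g: _send(self, g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        out = _make(self.data.transpose(*axes), (self,))
        inv = np.argsort(axes)
        out._backward = lambda g: _send(self, g.transpose(*inv))
        return out

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            _send(self, full)

        out._backward = bw
        return out

    def max_with(self, scalar: float):
        mask = self.data > scalar
        out = _make(np.maximum(self.data, scalar), (self,))
        out._backward = lambda g: _send(self, g * mask)
        return out

    # -- softmax --------------------------------------------------------------
    def log_softmax(self, axis: int):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        ls = shifted - lse
        out = _make(ls, (self,))
        soft = np.exp(ls)

        def bw(g):
            _send(self, g - soft * g.sum(axis=axis, keepdims=True))

        out._backward = bw
        return out

    def softmax(self, axis: int):
        return self.log_softmax(axis).exp()


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = tuple(p for p in parents if p.requires_grad or p._parents)
    return out


def _send(t: Tensor, g: np.ndarray) -> None:
    """Route a gradient to a parent, summing out broadcast dimensions."""
    if not (t.requires_grad or t._parents):
        return
    g = np.asarray(g)
    while g.ndim > t.data.ndim:
        g = g.sum(axis=0)
    for i, s in enumerate(t.data.shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    t._accumulate(g)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, b)
            _send(t, g[tuple(idx)])

    out._backward = bw
    return out


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           pad: int | None = None) -> Tensor:
    """3-D convolution, input (N,C,D,H,W), weight (F,C,kd,kh,kw).

    Default padding keeps odd kernels size-preserving at stride 1.
    """
    F, C, kd, kh, kw = w.data.shape
    if pad is None:
        pad = kd // 2
    s = stride
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kd, kh, kw), axis=(2, 3, 4))
    win = win[:, :, ::s, ::s, ::s]  # (N,C,Do,Ho,Wo,kd,kh,kw)
    out_data = np.tensordot(win, w.data, axes=([1, 5, 6, 7], [1, 2, 3, 4]))
    out_data = np.ascontiguousarray(out_data.transpose(0, 4, 1, 2, 3))
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = _make(out_data, parents)
    N = x.data.shape[0]
    Do, Ho, Wo = out_data.shape[2:]

    def bw(g):
        # weight grad: correlate input windows with output grad
        gw = np.tensordot(g, win, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
        _send(w, gw)
        if b is not None:
            _send(b, g.sum(axis=(0, 2, 3, 4)))
        if s == 1:
            # input grad = correlation of g with the spatially flipped kernel
            pg = kd - 1 - pad
            gp = np.pad(g, ((0, 0), (0, 0), (pg, pg), (pg, pg), (pg, pg)))
            wf = w.data[:, :, ::-1, ::-1, ::-1]
            wing = np.lib.stride_tricks.sliding_window_view(
                gp, (kd, kh, kw), axis=(2, 3, 4))
            gx = np.tensordot(wing, wf, axes=([1, 5, 6, 7], [0, 2, 3, 4]))
            gx = gx.transpose(0, 4, 1, 2, 3)
        else:
            # strided case: contract over filters, scatter per kernel offset
            gx_pad = np.zeros_like(xp)
            dcol = np.tensordot(g, w.data, axes=([1], [0]))
            dcol = np.ascontiguousarray(dcol.transpose(5, 6, 7, 0, 4, 1, 2, 3))
            for a in range(kd):
                for bb in range(kh):
                    for c in range(kw):
                        gx_pad[:, :, a:a + s * Do:s, bb:bb + s * Ho:s, c:c + s * Wo:s] += \
                            dcol[a, bb, c]
            gx = gx_pad[:, :, pad:-pad, pad:-pad, pad:-pad] if pad else gx_pad
        _send(x, gx)

    out._backward = bw
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of a (N,C,D,H,W) tensor."""
    d = x.data
    up = d.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)
    out = _make(up, (x,))
    N, C, D, H, W = d.shape

    def bw(g):
        g = g.reshape(N, C, D, 2, H, 2, W, 2).sum(axis=(3, 5, 7))
        _send(x, g)

    out._backward = bw
    return out


def stack_params(*tensors: Tensor) -> list[Tensor]:
    """Flatten a mix of tensors/iterables into a parameter list."""
    out: list[Tensor] = []
    for t in tensors:
        if isinstance(t, Tensor):
            out.append(t)
        else:
            out.extend(t)
    return out
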