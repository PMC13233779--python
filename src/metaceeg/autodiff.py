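"""Minimal reverse-mode automatic differentiation over numpy arrays.

The trainers in this package need gradients of gradients: the WGAN-GP
penalty term ``(||grad_x D(x)|| - 1)^2`` must itself be differentiated with
respect to the critic parameters.  To support that, every vector-Jacobian
product (VJP) below is expressed in terms of the same primitive operations,
so the backward pass builds a graph that can be differentiated again.

The op set is deliberately small: dense algebra, elementwise nonlinearities,
reductions, shape surgery, and a stride-1 1-D convolution whose VJPs are
themselves convolutions.  This is all the reduced-scale EEG generators and
critics require; it is not a general deep-learning framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "astensor", "grad", "concat", "conv1d"]


class Tensor:
    """A numpy array plus the recipe (parent tensors + VJP closures) that made it."""

    __slots__ = ("data", "parents")

    def __init__(self, data, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        # parents: tuple of (Tensor, vjp) where vjp maps the incoming cotangent
        # (a Tensor shaped like self) to a cotangent shaped like the parent.
        self.parents = tuple(parents)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape})"

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = astensor(other)
        out = Tensor(self.data + other.data,
                     [(self, lambda g: _unbroadcast(g, self.shape)),
                      (other, lambda g: _unbroadcast(g, other.shape))])
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)
        return Tensor(self.data * other.data,
                      [(self, lambda g: _unbroadcast(g * other, self.shape)),
                       (other, lambda g: _unbroadcast(g * self, other.shape))])

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * astensor(other) ** -1.0

    def __rtruediv__(self, other):
        return astensor(other) * self ** -1.0

    def __pow__(self, p):
        p = float(p)
        base = self
        return Tensor(self.data ** p,
                      [(self, lambda g: g * (p * base ** (p - 1.0)))])

    def __matmul__(self, other):
        other = astensor(other)
        a, b = self, other
        return Tensor(a.data @ b.data,
                      [(a, lambda g: g @ b.T), (b, lambda g: a.T @ g)])

    @property
    def T(self):
        return transpose(self)

    # -- convenience wrappers ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in _axes(axis, self.ndim)])
        return tsum(self, axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def detach(self):
        return Tensor(self.data)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _axes(axis, ndim):
    if axis is None:
        return tuple(range(ndim))
    if isinstance(axis, int):
        axis = (axis,)
    return tuple(a % ndim for a in axis)


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Reduce a cotangent back to the shape of a broadcast operand."""
    if g.shape == tuple(shape):
        return g
    # sum over prepended axes
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    # sum over axes that were size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return reshape(g, tuple(shape))


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def tsum(x: Tensor, axis=None, keepdims=False) -> Tensor:
    x = astensor(x)
    axes = _axes(axis, x.ndim)
    out_data = x.data.sum(axis=axes, keepdims=keepdims)

    def vjp(g: Tensor) -> Tensor:
        gg = g
        if not keepdims:
            kshape = tuple(1 if i in axes else s for i, s in enumerate(x.shape))
            gg = reshape(gg, kshape)
        return broadcast_to(gg, x.shape)

    return Tensor(out_data, [(x, vjp)])


def broadcast_to(x: Tensor, shape) -> Tensor:
    x = astensor(x)
    shape = tuple(shape)
    if x.shape == shape:
        return x
    return Tensor(np.broadcast_to(x.data, shape).copy(),
                  [(x, lambda g: _unbroadcast(g, x.shape))])


def reshape(x: Tensor, shape) -> Tensor:
    x = astensor(x)
    shape = tuple(shape)
    return Tensor(x.data.reshape(shape),
                  [(x, lambda g: reshape(g, x.shape))])


def transpose(x: Tensor, axes=None) -> Tensor:
    x = astensor(x)
    if axes is None:
        axes = tuple(reversed(range(x.ndim)))
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return Tensor(x.data.transpose(axes), [(x, lambda g: transpose(g, inv))])


def exp(x: Tensor) -> Tensor:
    x = astensor(x)
    out = Tensor(np.exp(x.data))
    out.parents = ((x, lambda g: g * out),)
    return out


def log(x: Tensor) -> Tensor:
    x = astensor(x)
    return Tensor(np.log(x.data), [(x, lambda g: g * x ** -1.0)])


def sqrt(x: Tensor) -> Tensor:
    return x ** 0.5


def tanh(x: Tensor) -> Tensor:
    x = astensor(x)
    out = Tensor(np.tanh(x.data))
    out.parents = ((x, lambda g: g * (1.0 - out * out)),)
    return out


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    x = astensor(x)
    mask = np.where(x.data > 0, 1.0, slope)  # constant a.e.
    return Tensor(x.data * mask, [(x, lambda g: g * Tensor(mask))])


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clip with straight-through-zero gradient outside [lo, hi]."""
    x = astensor(x)
    mask = ((x.data >= lo) & (x.data <= hi)).astype(np.float64)
    return Tensor(np.clip(x.data, lo, hi), [(x, lambda g: g * Tensor(mask))])


def concat(tensors, axis=0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    axis = axis % tensors[0].ndim
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)

    def make_vjp(i):
        return lambda g: narrow(g, axis, int(offsets[i]), sizes[i])

    return Tensor(out_data, [(t, make_vjp(i)) for i, t in enumerate(tensors)])


def narrow(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice along one axis; VJP zero-pads back."""
    x = astensor(x)
    axis = axis % x.ndim
    idx = [slice(None)] * x.ndim
    idx[axis] = slice(start, start + length)
    total = x.shape[axis]

    def vjp(g: Tensor) -> Tensor:
        return pad_axis(g, axis, start, total - start - length)

    return Tensor(x.data[tuple(idx)], [(x, vjp)])


def pad_axis(x: Tensor, axis: int, before: int, after: int) -> Tensor:
    x = astensor(x)
    axis = axis % x.ndim
    widths = [(0, 0)] * x.ndim
    widths[axis] = (before, after)

    def vjp(g: Tensor) -> Tensor:
        return narrow(g, axis, before, x.shape[axis])

    return Tensor(np.pad(x.data, widths), [(x, vjp)])


def flip_last(x: Tensor) -> Tensor:
    x = astensor(x)
    return Tensor(x.data[..., ::-1].copy(), [(x, lambda g: flip_last(g))])


def conv1d(x: Tensor, w: Tensor, pad: int = 0) -> Tensor:
    """Stride-1 cross-correlation: x [B,C,L], w [O,C,K] -> [B,O,L+2*pad-K+1].

    Both VJPs are themselves conv1d calls, so second derivatives (needed for
    the gradient penalty) come for free.
    """
    x, w = astensor(x), astensor(w)
    B, C, L = x.shape
    O, Cw, K = w.shape
    assert C == Cw, "channel mismatch"
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)  # [B,C,T,K]
    out = np.einsum("bctk,ock->bot", win, w.data, optimize=True)

    def vjp_x(g: Tensor) -> Tensor:
        wt = flip_last(transpose(w, (1, 0, 2)))  # [C,O,K] flipped
        full = conv1d(g, wt, pad=K - 1)          # length L + 2*pad
        return narrow(full, 2, pad, L)

    def vjp_w(g: Tensor) -> Tensor:
        xp_t = pad_axis(x, 2, pad, pad)
        a = transpose(xp_t, (1, 0, 2))           # [C,B,Lp]
        v = transpose(g, (1, 0, 2))              # [O,B,T]
        dw = conv1d(a, v, pad=0)                 # [C,O,K]
        return transpose(dw, (1, 0, 2))

    return Tensor(out, [(x, vjp_x), (w, vjp_w)])


# ---------------------------------------------------------------------------
# reverse pass
# ---------------------------------------------------------------------------

def _topo(output: Tensor):
    order, seen = [], set()
    stack = [(output, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node.parents:
            stack.append((parent, False))
    return order  # children after parents


def grad(output: Tensor, wrt) -> list[Tensor]:
    """Cotangents of a scalar `output` w.r.t. each tensor in `wrt`.

    The returned tensors carry their own graphs, so they can be fed back
    into `grad` for higher-order derivatives.
    """
    single = isinstance(wrt, Tensor)
    wrt_list = [wrt] if single else list(wrt)
    if output.data.size != 1:
        raise ValueError("grad expects a scalar output")

    cot: dict[int, Tensor] = {id(output): Tensor(np.ones_like(output.data))}
    for node in reversed(_topo(output)):
        g = cot.get(id(node))
        if g is None:
            continue
        for parent, vjp in node.parents:
            contrib = vjp(g)
            prev = cot.get(id(parent))
            cot[id(parent)] = contrib if prev is None else prev + contrib

    out = [cot.get(id(t), Tensor(np.zeros_like(t.data))) for t in wrt_list]
    return out[0] if single else out
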