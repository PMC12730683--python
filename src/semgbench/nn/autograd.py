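"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to it;
:meth:`Tensor.backward` walks the tape in reverse topological order and
accumulates gradients. The operation set is exactly what the benchmark's two
classifiers need: broadcast arithmetic, (batched) matmul, reshape/transpose/
slicing/concatenation, reductions, elementwise nonlinearities (ReLU, exact
erf-based GELU), a softmax primitive, 2-D convolution and average pooling,
and a fused softmax-cross-entropy loss. Every primitive's gradient is
verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _special

__all__ = ["Tensor", "concat", "softmax_cross_entropy", "conv2d", "avg_pool2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @classmethod
    def _from_op(cls, data, parents, backward):
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff core --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad or pg is None:
                    continue
                if parent._backward is None:  # leaf
                    parent.grad = pg if parent.grad is None else parent.grad + pg
                else:
                    acc = grads.get(id(parent))
                    grads[id(parent)] = pg if acc is None else acc + pg

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        return Tensor._from_op(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        return Tensor._from_op(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return Tensor._from_op(
            self.data / other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __pow__(self, exponent: float):
        return Tensor._from_op(
            self.data**exponent,
            (self,),
            lambda g: (g * exponent * self.data ** (exponent - 1),),
        )

    def __matmul__(self, other):
        other = self._wrap(other)
        out = self.data @ other.data

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        return Tensor._from_op(out, (self, other), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape
        return Tensor._from_op(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(orig),)
        )

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        return Tensor._from_op(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, key):
        def backward(g):
            out = np.zeros_like(self.data)
            np.add.at(out, key, g)
            return (out,)

        return Tensor._from_op(self.data[key], (self,), backward)

    def broadcast_to(self, shape):
        orig = self.shape
        return Tensor._from_op(
            np.broadcast_to(self.data, shape).copy(),
            (self,),
            lambda g: (_unbroadcast(g, orig),),
        )

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._from_op(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor._from_op(self.data * mask, (self,), lambda g: (g * mask,))

    def exp(self):
        out = np.exp(self.data)
        return Tensor._from_op(out, (self,), lambda g: (g * out,))

    def log(self):
        return Tensor._from_op(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor._from_op(out, (self,), lambda g: (g * 0.5 / out,))

    def gelu(self):
        """Exact Gaussian-error GELU: x * Phi(x) with Phi the standard normal CDF."""
        x = self.data
        phi = 0.5 * (1.0 + _special.erf(x / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * x**2) / np.sqrt(2.0 * np.pi)
        return Tensor._from_op(x * phi, (self,), lambda g: (g * (phi + x * pdf),))

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return (s * (g - dot),)

        return Tensor._from_op(s, (self,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._from_op(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def softmax_cross_entropy(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy of row softmax vs one-hot targets."""
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - logsumexp
    n = logits.data.shape[0]
    loss = -(onehot * logp).sum() / n

    def backward(g):
        p = np.exp(logp)
        return (g * (p - onehot) / n,)

    return Tensor._from_op(loss, (logits,), backward)


# -- convolution and pooling (NHWC layout) ------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Extract all (kh, kw) patches: (N, H, W, C) -> (N, Ho, Wo, kh, kw, C)."""
    N, H, W, C = x.shape
    Ho, Wo = H - kh + 1, W - kw + 1
    s0, s1, s2, s3 = x.strides
    return np.lib.stride_tricks.as_strided(
        x, (N, Ho, Wo, kh, kw, C), (s0, s1, s2, s1, s2, s3), writeable=False
    )


def conv2d(x: Tensor, w: Tensor, b: Tensor, padding: str = "valid") -> Tensor:
    """2-D cross-correlation with stride 1.

    ``x`` is (N, H, W, C_in), ``w`` is (kh, kw, C_in, C_out), ``b`` is
    (C_out,). ``padding='same'`` zero-pads so the spatial shape is preserved
    (left/top pad = (k - 1) // 2).
    """
    kh, kw, cin, cout = w.shape
    if padding == "same":
        pt, pl = (kh - 1) // 2, (kw - 1) // 2
        pb, pr = kh - 1 - pt, kw - 1 - pl
    elif padding == "valid":
        pt = pb = pl = pr = 0
    else:
        raise ValueError(f"unknown padding {padding!r}")
    xp = np.pad(x.data, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    N, Hp, Wp, _ = xp.shape
    Ho, Wo = Hp - kh + 1, Wp - kw + 1
    if Ho <= 0 or Wo <= 0:
        raise ValueError(
            f"conv2d: kernel ({kh}x{kw}) larger than padded input ({Hp}x{Wp})"
        )
    cols = _im2col(xp, kh, kw).reshape(N, Ho, Wo, kh * kw * cin)
    wmat = w.data.reshape(kh * kw * cin, cout)
    out = cols @ wmat + b.data

    def backward(g):
        # g: (N, Ho, Wo, cout)
        gmat = g.reshape(-1, cout)
        gw = (cols.reshape(-1, kh * kw * cin).T @ gmat).reshape(w.shape)
        gb = gmat.sum(axis=0)
        dcols = (g @ wmat.T).reshape(N, Ho, Wo, kh, kw, cin)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, i : i + Ho, j : j + Wo, :] += dcols[:, :, :, i, j, :]
        dx = dxp[:, pt : Hp - pb, pl : Wp - pr, :]
        return dx, gw, gb

    return Tensor._from_op(out, (x, w, b), backward)


def avg_pool2d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping average pooling with floor-mode edges.

    Trailing rows/columns that do not fill a full ``size x size`` cell are
    dropped (floor division), matching the shape convention that yields the
    benchmark's token counts (5 for Myo, 19 for DB3).
    """
    N, H, W, C = x.shape
    Ho, Wo = H // size, W // size
    if Ho == 0 or Wo == 0:
        raise ValueError(f"avg_pool2d: input {H}x{W} smaller than pool size {size}")
    xc = x.data[:, : Ho * size, : Wo * size, :]
    out = xc.reshape(N, Ho, size, Wo, size, C).mean(axis=(2, 4))

    def backward(g):
        dx = np.zeros_like(x.data)
        expanded = np.repeat(np.repeat(g, size, axis=1), size, axis=2) / (size * size)
        dx[:, : Ho * size, : Wo * size, :] = expanded
        return (dx,)

    return Tensor._from_op(out, (x,), backward)
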