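"""Neural-network layers built on the autograd engine.

Layout convention is NHWC (batch, height=channels, width=time, depth), the
same convention the benchmark's layer tables are written in. Weight
initialization is Glorot-uniform for conv/dense kernels, zeros for biases,
and truncated-normal (sigma = 0.02) for class/positional tokens; every layer
draws from an explicitly passed generator so model construction is seeded.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, avg_pool2d, concat, conv2d

__all__ = [
    "Module",
    "Dense",
    "Conv2D",
    "AvgPool2D",
    "Dropout",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "TransformerBlock",
]


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Base class with recursive parameter collection and train/eval modes."""

    def __init__(self) -> None:
        self.training = True

    def _children(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list[Tensor]:
        params = [
            v for v in self.__dict__.values()
            if isinstance(v, Tensor) and v.requires_grad
        ]
        for child in self._children():
            params.extend(child.parameters())
        return params

    def train(self) -> "Module":
        self.training = True
        for child in self._children():
            child.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for child in self._children():
            child.eval()
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def get_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state length does not match parameter count")
        for p, s in zip(params, state):
            p.data = s.copy()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        self.w = Tensor(_glorot(rng, (n_in, n_out), n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2D(Module):
    def __init__(
        self,
        in_depth: int,
        filters: int,
        kernel: tuple[int, int],
        padding: str,
        rng: np.random.Generator,
    ):
        super().__init__()
        kh, kw = kernel
        self.padding = padding
        fan_in = kh * kw * in_depth
        fan_out = kh * kw * filters
        self.w = Tensor(
            _glorot(rng, (kh, kw, in_depth, filters), fan_in, fan_out),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(filters), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, padding=self.padding)


class AvgPool2D(Module):
    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def __call__(self, x: Tensor) -> Tensor:
        return avg_pool2d(x, self.size)


class Dropout(Module):
    """Inverted dropout; active only in training mode, seeded via the model rng."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        return xn * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Scaled dot-product attention over h heads of width d/h.

    The per-head key width d_k = d / h enters the 1/sqrt(d_k) temperature.
    Attention probabilities get dropout in training mode.
    """

    def __init__(self, dim: int, n_heads: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads != 0:
            raise ValueError(f"token dim {dim} not divisible by {n_heads} heads")
        self.dim, self.n_heads = dim, n_heads
        self.head_dim = dim // n_heads
        self.wq = Dense(dim, dim, rng)
        self.wk = Dense(dim, dim, rng)
        self.wv = Dense(dim, dim, rng)
        self.wo = Dense(dim, dim, rng)
        self.attn_dropout = Dropout(dropout, rng)

    def _split_heads(self, t: Tensor, n: int, seq: int) -> Tensor:
        return t.reshape(n, seq, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor) -> Tensor:
        n, seq, _ = x.shape
        q = self._split_heads(self.wq(x), n, seq)  # (N, h, T, dh)
        k = self._split_heads(self.wk(x), n, seq)
        v = self._split_heads(self.wv(x), n, seq)
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.head_dim))
        probs = self.attn_dropout(logits.softmax(axis=-1))
        ctx = probs @ v  # (N, h, T, dh)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(n, seq, self.dim)
        return self.wo(ctx)


class TransformerBlock(Module):
    """Pre-norm encoder layer: LN -> MHSA -> residual, LN -> MLP -> residual."""

    def __init__(
        self,
        dim: int,
        n_heads: int,
        mlp_hidden: int,
        dropout: float,
        rng: np.random.Generator,
    ):
        super().__init__()
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, dropout, rng)
        self.drop1 = Dropout(dropout, rng)
        self.ln2 = LayerNorm(dim)
        self.fc1 = Dense(dim, mlp_hidden, rng)
        self.drop2 = Dropout(dropout, rng)
        self.fc2 = Dense(mlp_hidden, dim, rng)
        self.drop3 = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.drop1(self.attn(self.ln1(x)))
        h = self.drop2(self.fc1(self.ln2(x)).gelu())
        return x + self.drop3(self.fc2(h))


def prepend_class_token(tokens: Tensor, cls: Tensor) -> Tensor:
    """Broadcast a (1, 1, d) class token over the batch and prepend it."""
    n = tokens.shape[0]
    return concat([cls.broadcast_to((n, 1, cls.shape[2])), tokens], axis=1)
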