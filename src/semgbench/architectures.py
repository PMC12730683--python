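"""The two classifiers: an Atzori-style CNN and a conv-stem Transformer (CViT).

Both consume class-pure windows shaped (channels x time x 1). The CNN is the
classical four-conv design: conv 1x12 valid, conv 3x3 valid, average pool
2x2, conv 5x5 same, average pool 2x2, conv 9x1 same (ReLU after each conv),
flatten, dense softmax over the six gesture classes. Pooling uses floor
division without padding — the convention under which the stem yields 4
(Myo) and 18 (DB3) spatial positions and the CNN-Myo trainable parameter
total is exactly 99,398.

The CViT reuses the conv stem (truncated before flatten) as a local feature
extractor: each spatial position of the stem output (depth 64) becomes one
patch token, linearly projected to d = 64; a learnable class token is
prepended and learnable positional embeddings (class token included) are
added. Four pre-norm encoder layers follow, each LayerNorm -> 8-head
self-attention -> residual -> LayerNorm -> MLP(256, GELU, dropout 0.1) ->
residual, with per-head width d/h = 8 inside the 1/sqrt(d_k) temperature.
The class token feeds a GELU dense head (width 128, dropout) and the final
softmax layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import DatasetProfile
from .nn import (
    AvgPool2D,
    Conv2D,
    Dense,
    Dropout,
    LayerNorm,
    Module,
    Tensor,
    TransformerBlock,
)
from .nn.layers import prepend_class_token

__all__ = [
    "stem_output_shape",
    "AtzoriCNN",
    "ConvViT",
    "build_cnn",
    "build_cvit",
    "count_parameters",
    "scaled_dot_attention",
    "AttentionWeights",
    "multi_head_attention",
    "layer_summary",
]

#: (filters, (kh, kw), padding) for the four stem convolutions.
_STEM_CONVS = (
    (32, (1, 12), "valid"),
    (32, (3, 3), "valid"),
    (64, (5, 5), "same"),
    (64, (9, 1), "same"),
)


def stem_output_shape(profile: DatasetProfile) -> tuple[int, int, int]:
    """Propagate (channels, window, 1) through the conv stem.

    Valid convs shrink each dimension by k - 1, same convs preserve it, and
    each 2x2 average pool floor-divides. Raises if any intermediate
    dimension is non-positive.
    """
    h, w = profile.n_channels, profile.window_len

    def check(h, w, stage):
        if h <= 0 or w <= 0:
            raise ValueError(
                f"non-positive feature-map shape ({h}, {w}) after {stage} for "
                f"input {profile.n_channels}x{profile.window_len}"
            )

    h, w = h - 0, w - 11  # conv1 1x12 valid
    check(h, w, "conv1 (1x12 valid)")
    h, w = h - 2, w - 2  # conv2 3x3 valid
    check(h, w, "conv2 (3x3 valid)")
    h, w = h // 2, w // 2  # pool1
    check(h, w, "pool1 (2x2 avg)")
    # conv3 5x5 same: shape preserved
    h, w = h // 2, w // 2  # pool2
    check(h, w, "pool2 (2x2 avg)")
    # conv4 9x1 same: shape preserved
    return h, w, 64


class _ConvStem(Module):
    """Four-conv feature extractor shared by the CNN and the CViT."""

    def __init__(self, profile: DatasetProfile, rng: np.random.Generator):
        super().__init__()
        stem_output_shape(profile)  # validate shapes before allocating
        self.conv1 = Conv2D(1, 32, (1, 12), "valid", rng)
        self.conv2 = Conv2D(32, 32, (3, 3), "valid", rng)
        self.pool1 = AvgPool2D(2)
        self.conv3 = Conv2D(32, 64, (5, 5), "same", rng)
        self.pool2 = AvgPool2D(2)
        self.conv4 = Conv2D(64, 64, (9, 1), "same", rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.conv1(x).relu()
        x = self.conv2(x).relu()
        x = self.pool1(x)
        x = self.conv3(x).relu()
        x = self.pool2(x)
        return self.conv4(x).relu()


def _as_input(x: np.ndarray) -> Tensor:
    """Accept (N, ch, W) or (N, ch, W, 1) windows, return an NHWC tensor."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 3:
        x = x[..., None]
    if x.ndim != 4 or x.shape[-1] != 1:
        raise ValueError(f"expected windows (N, channels, W[, 1]), got {x.shape}")
    return Tensor(x)


class AtzoriCNN(Module):
    """The classical CNN classifier."""

    def __init__(self, profile: DatasetProfile, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.profile = profile
        self.stem = _ConvStem(profile, rng)
        h, w, depth = stem_output_shape(profile)
        self.flat_dim = h * w * depth
        self.dense = Dense(self.flat_dim, profile.n_classes, rng)

    def __call__(self, x: Tensor) -> Tensor:
        feats = self.stem(x)
        n = feats.shape[0]
        return self.dense(feats.reshape(n, self.flat_dim))

    def forward(self, x: np.ndarray) -> Tensor:
        return self(_as_input(x))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        was_training = self.training
        self.eval()
        try:
            return self.forward(x).softmax(axis=-1).data
        finally:
            if was_training:
                self.train()

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=-1)


class ConvViT(Module):
    """Conv-stem + Transformer-encoder classifier with a class token."""

    def __init__(
        self,
        profile: DatasetProfile,
        token_dim: int = 64,
        n_layers: int = 4,
        n_heads: int = 8,
        mlp_hidden: int = 256,
        dropout: float = 0.1,
        head_hidden: int = 128,
        seed: int = 0,
    ):
        super().__init__()
        if token_dim % n_heads != 0:
            raise ValueError(
                f"token dim {token_dim} must be divisible by n_heads {n_heads}"
            )
        rng = np.random.default_rng(seed)
        self.profile = profile
        self.token_dim = token_dim
        self.stem = _ConvStem(profile, rng)
        h, w, depth = stem_output_shape(profile)
        self.n_patches = h * w
        self.n_tokens = self.n_patches + 1  # + class token
        self.proj = Dense(depth, token_dim, rng)
        self.cls_token = Tensor(_rng_token(rng, (1, 1, token_dim)), requires_grad=True)
        self.pos_embed = Tensor(
            _rng_token(rng, (1, self.n_tokens, token_dim)), requires_grad=True
        )
        self.blocks = [
            TransformerBlock(token_dim, n_heads, mlp_hidden, dropout, rng)
            for _ in range(n_layers)
        ]
        self.norm = LayerNorm(token_dim)
        self.head_fc = Dense(token_dim, head_hidden, rng)
        self.head_drop = Dropout(dropout, rng)
        self.head_out = Dense(head_hidden, profile.n_classes, rng)

    def tokenize(self, x: Tensor) -> Tensor:
        feats = self.stem(x)  # (N, h, w, 64)
        n = feats.shape[0]
        tokens = self.proj(feats.reshape(n, self.n_patches, feats.shape[-1]))
        tokens = prepend_class_token(tokens, self.cls_token)
        return tokens + self.pos_embed

    def __call__(self, x: Tensor) -> Tensor:
        t = self.tokenize(x)
        for block in self.blocks:
            t = block(t)
        cls = self.norm(t)[:, 0, :]
        h = self.head_drop(self.head_fc(cls).gelu())
        return self.head_out(h)

    def forward(self, x: np.ndarray) -> Tensor:
        return self(_as_input(x))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        was_training = self.training
        self.eval()
        try:
            return self.forward(x).softmax(axis=-1).data
        finally:
            if was_training:
                self.train()

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=-1)


def _rng_token(rng: np.random.Generator, shape, sigma: float = 0.02) -> np.ndarray:
    return np.clip(rng.standard_normal(shape) * sigma, -2 * sigma, 2 * sigma)


def build_cnn(profile: DatasetProfile, seed: int = 0) -> AtzoriCNN:
    return AtzoriCNN(profile, seed=seed)


def build_cvit(profile: DatasetProfile, seed: int = 0, **kw) -> ConvViT:
    return ConvViT(profile, seed=seed, **kw)


def count_parameters(model: Module) -> int:
    """Exact count of trainable scalars."""
    return model.n_parameters()


# -- functional attention (reference forms) -----------------------------------

def scaled_dot_attention(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray, d_k: float
) -> np.ndarray:
    """softmax(Q K^T / sqrt(d_k)) V on plain arrays; rows of the attention
    matrix sum to 1."""
    if d_k <= 0:
        raise ValueError(f"d_k must be positive, got {d_k}")
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    if K.shape[0] != V.shape[0]:
        raise ValueError("K and V must have the same number of rows")
    logits = Q @ K.T / np.sqrt(d_k)
    logits -= logits.max(axis=-1, keepdims=True)
    w = np.exp(logits)
    w /= w.sum(axis=-1, keepdims=True)
    return w @ V


@dataclass
class AttentionWeights:
    """Per-head projections W_i^Q/K/V (each d x d_h) and output W^O (h d_h x d)."""

    wq: list[np.ndarray]
    wk: list[np.ndarray]
    wv: list[np.ndarray]
    wo: np.ndarray

    def __post_init__(self) -> None:
        h = len(self.wq)
        if not (len(self.wk) == len(self.wv) == h):
            raise ValueError("wq, wk, wv must list one matrix per head")
        d_h = self.wq[0].shape[1]
        if self.wo.shape[0] != h * d_h:
            raise ValueError("wo rows must equal h * d_h")


def multi_head_attention(x: np.ndarray, weights: AttentionWeights, h: int) -> np.ndarray:
    """Heads computed independently on per-head projections, concatenated,
    then projected by W^O."""
    if h != len(weights.wq):
        raise ValueError(f"h={h} but weights carry {len(weights.wq)} heads")
    heads = []
    for wq, wk, wv in zip(weights.wq, weights.wk, weights.wv):
        d_k = wq.shape[1]
        heads.append(scaled_dot_attention(x @ wq, x @ wk, x @ wv, d_k))
    return np.concatenate(heads, axis=-1) @ weights.wo


# -- model description --------------------------------------------------------

def layer_summary(model: Module) -> list[tuple[str, str, int]]:
    """Rows of (layer name, output shape, trainable parameters)."""
    if isinstance(model, AtzoriCNN):
        return _cnn_summary(model)
    if isinstance(model, ConvViT):
        return _cvit_summary(model)
    raise TypeError(f"no summary for {type(model).__name__}")


def _stem_rows(profile: DatasetProfile) -> list[tuple[str, str, int]]:
    h, w = profile.n_channels, profile.window_len
    rows = []
    depth = 1
    specs = [
        ("conv1 (1x12, valid)", _STEM_CONVS[0]),
        ("conv2 (3x3, valid)", _STEM_CONVS[1]),
        ("pool1 (avg 2x2)", None),
        ("conv3 (5x5, same)", _STEM_CONVS[2]),
        ("pool2 (avg 2x2)", None),
        ("conv4 (9x1, same)", _STEM_CONVS[3]),
    ]
    for name, spec in specs:
        if spec is None:
            h, w = h // 2, w // 2
            rows.append((name, f"({h}, {w}, {depth})", 0))
        else:
            filters, (kh, kw), padding = spec
            if padding == "valid":
                h, w = h - kh + 1, w - kw + 1
            params = filters * (kh * kw * depth) + filters
            depth = filters
            rows.append((name, f"({h}, {w}, {depth})", params))
    return rows


def _cnn_summary(model: AtzoriCNN) -> list[tuple[str, str, int]]:
    rows = _stem_rows(model.profile)
    rows.append(("flatten", f"({model.flat_dim},)", 0))
    n_out = model.profile.n_classes
    rows.append(
        ("dense (softmax)", f"({n_out},)", (model.flat_dim + 1) * n_out)
    )
    return rows


def _cvit_summary(model: ConvViT) -> list[tuple[str, str, int]]:
    rows = _stem_rows(model.profile)
    d = model.token_dim
    rows.append(("patch projection", f"({model.n_patches}, {d})", (64 + 1) * d))
    rows.append(("class token", f"(1, {d})", d))
    rows.append(("positional embeddings", f"({model.n_tokens}, {d})", model.n_tokens * d))
    for i, block in enumerate(model.blocks, start=1):
        rows.append(
            (f"encoder layer {i}", f"({model.n_tokens}, {d})", block.n_parameters())
        )
    rows.append(("final layernorm", f"({model.n_tokens}, {d})", model.norm.n_parameters()))
    rows.append(
        ("head dense (GELU)", f"({model.head_fc.n_out},)",
         (d + 1) * model.head_fc.n_out)
    )
    n_out = model.profile.n_classes
    rows.append(
        ("head softmax", f"({n_out},)", (model.head_fc.n_out + 1) * n_out)
    )
    return rows
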