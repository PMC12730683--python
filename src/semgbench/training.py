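"""Training loop and the subject-specific experimental protocol.

The optimizer/callback regime follows the benchmark settings: the CNN trains
with SGD (lr 0.001, momentum 0.9), batch 15, up to 100 epochs; the CViT
with Adam (lr 0.001), batch 32, up to 200 epochs. Both use early stopping
on validation loss (patience 15), learning-rate reduction on plateau
(factor 0.5, patience 7, floor 1e-5) and best-validation checkpointing:
the returned weights are always those of the epoch with minimal validation
loss, never the last epoch.

The subject-specific protocol repeats, for each of ``n_experiments``
independently seeded runs: segment -> balance -> split by repetition ->
fit standardization on the train windows (per-channel global statistics by
default; the class-conditional variant is available via PipelineOptions)
and apply it to both sides -> (optional mu-law companding) -> carve a
stratified validation fold out of the train windows for early stopping ->
train -> evaluate exactly once on the held-out repetitions. Held-out
windows never reach the optimizer; the protocol asserts this from the
repetition provenance tags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .architectures import build_cnn, build_cvit
from .containers import DatasetProfile, Recording, WindowSet
from .evaluation import MetricsReport, confusion_and_metrics
from .nn import Adam, SGD, softmax_cross_entropy
from .preprocessing import (
    SplitSpec,
    balance_classes,
    mu_law_normalize,
    rescale_to_unit,
    segment_windows,
    split_by_repetition,
    standardize_windows,
    standardize_windows_global,
)

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "RunHistory", "train", "run_subject_protocol"]


@dataclass
class TrainConfig:
    """Optimizer and callback settings for one model kind."""

    model_kind: str = "cnn"  # "cnn" | "cvit"
    optimizer: str = "sgd"  # "sgd" | "adam"
    learning_rate: float = 1e-3
    momentum: float = 0.9
    batch_size: int = 15
    max_epochs: int = 100
    early_stop_patience: int = 15
    lr_factor: float = 0.5
    lr_patience: int = 7
    min_lr: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in ("cnn", "cvit"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("early_stop_patience must be < max_epochs")

    @classmethod
    def for_cnn(cls, **kw) -> "TrainConfig":
        base = dict(model_kind="cnn", optimizer="sgd", learning_rate=1e-3,
                    momentum=0.9, batch_size=15, max_epochs=100)
        base.update(kw)
        return cls(**base)

    @classmethod
    def for_cvit(cls, **kw) -> "TrainConfig":
        base = dict(model_kind="cvit", optimizer="adam", learning_rate=1e-3,
                    batch_size=32, max_epochs=200)
        base.update(kw)
        return cls(**base)

    @classmethod
    def for_kind(cls, kind: str, **kw) -> "TrainConfig":
        return cls.for_cnn(**kw) if kind == "cnn" else cls.for_cvit(**kw)

    def build_model(self, profile: DatasetProfile, seed: int | None = None):
        seed = self.seed if seed is None else seed
        if self.model_kind == "cnn":
            return build_cnn(profile, seed=seed)
        return build_cvit(profile, seed=seed)

    def build_optimizer(self, model):
        if self.optimizer == "sgd":
            return SGD(model.parameters(), lr=self.learning_rate, momentum=self.momentum)
        if self.optimizer == "adam":
            return Adam(model.parameters(), lr=self.learning_rate)
        raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class RunHistory:
    """Per-epoch curves plus the best (minimum validation loss) epoch index."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def _eval_loss_acc(model, x: np.ndarray, y: np.ndarray, n_classes: int,
                   chunk: int = 512) -> tuple[float, float]:
    was_training = model.training
    model.eval()
    try:
        losses, correct = [], 0
        onehot = _one_hot(y, n_classes)
        for i in range(0, len(x), chunk):
            logits = model.forward(x[i : i + chunk])
            loss = softmax_cross_entropy(logits, onehot[i : i + chunk])
            losses.append(loss.data.item() * (min(i + chunk, len(x)) - i))
            correct += int((logits.data.argmax(axis=-1) == y[i : i + chunk]).sum())
        return sum(losses) / len(x), correct / len(x)
    finally:
        if was_training:
            model.train()


def train(model, train_ws: WindowSet, val_ws: WindowSet, cfg: TrainConfig):
    """Train a model; return (model with best-epoch weights, RunHistory)."""
    if len(train_ws) == 0 or len(val_ws) == 0:
        raise ValueError("train and validation sets must be non-empty")
    n_classes = train_ws.profile.n_classes
    missing = set(np.unique(train_ws.labels)) - set(np.unique(val_ws.labels))
    if missing:
        logger.warning("validation set missing class(es) %s", sorted(missing))

    x_tr, y_tr = train_ws.data, train_ws.labels
    x_val, y_val = val_ws.data, val_ws.labels
    onehot_tr = _one_hot(y_tr, n_classes)
    opt = cfg.build_optimizer(model)
    rng = np.random.default_rng(cfg.seed)

    history = RunHistory()
    best_state = model.get_state()
    best_val = np.inf
    since_best = 0
    since_lr = 0

    model.train()
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_tr))
        loss_sum = 0.0
        correct = 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            logits = model.forward(x_tr[idx])
            loss = softmax_cross_entropy(logits, onehot_tr[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"NaN/inf training loss at epoch {epoch}, batch {i // cfg.batch_size} "
                    f"(lr={opt.lr:g}); aborting"
                )
            model.zero_grad()
            loss.backward()
            opt.step()
            loss_sum += loss.data.item() * len(idx)
            correct += int((logits.data.argmax(axis=-1) == y_tr[idx]).sum())
        val_loss, val_acc = _eval_loss_acc(model, x_val, y_val, n_classes)

        history.train_loss.append(loss_sum / len(x_tr))
        history.train_accuracy.append(correct / len(x_tr))
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        history.learning_rate.append(opt.lr)

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = model.get_state()
            history.best_epoch = epoch
            since_best = 0
            since_lr = 0
        else:
            since_best += 1
            since_lr += 1
            if since_best >= cfg.early_stop_patience:
                history.stopped_early = True
                break
            if since_lr >= cfg.lr_patience and opt.lr > cfg.min_lr:
                opt.lr = max(opt.lr * cfg.lr_factor, cfg.min_lr)
                since_lr = 0

    model.set_state(best_state)  # best-validation checkpoint restore
    model.eval()
    return model, history


@dataclass
class PipelineOptions:
    """Preprocessing choices threaded through the protocol.

    Standardization is fit on train windows and applied to test windows.
    The default is class-agnostic per-channel scaling, which is applicable
    to unlabeled test data; ``per_class_standardization=True`` switches to
    class-conditional scaling (which requires test labels and flattens
    between-class amplitude structure). mu-law companding is off for the
    Myo-style pipeline and available for the DB3-style one; when on, each
    channel is rescaled by its training-set max |x| before companding so the
    transform's domain holds on test data.
    """

    per_class_standardization: bool = False
    use_mu_law: bool = False
    mu: float = 255.0


def _preprocess_split(
    ws: WindowSet, split: SplitSpec, opts: PipelineOptions, seed: int
) -> tuple[WindowSet, WindowSet]:
    ws = balance_classes(ws, seed=seed)
    train_ws, test_ws = split_by_repetition(ws, split)
    if opts.per_class_standardization:
        train_ws, params = standardize_windows(train_ws)
        test_ws, _ = standardize_windows(test_ws, params)
    else:
        train_ws, params = standardize_windows_global(train_ws)
        test_ws, _ = standardize_windows_global(test_ws, params)
    if opts.use_mu_law:
        flat = train_ws.data.transpose(1, 0, 2).reshape(ws.profile.n_channels, -1)
        scale = np.max(np.abs(flat), axis=1)[None, :, None]
        scale = np.where(scale == 0, 1.0, scale)
        tr, _ = rescale_to_unit(train_ws.data, scale=scale)
        te, _ = rescale_to_unit(test_ws.data, scale=scale)
        train_ws.data = mu_law_normalize(tr, mu=opts.mu)
        test_ws.data = mu_law_normalize(te, mu=opts.mu)
    return train_ws, test_ws


def run_subject_protocol(
    rec: Recording,
    profile: DatasetProfile,
    split: SplitSpec,
    cfg: TrainConfig,
    n_experiments: int = 14,
    k_folds: int = 5,
    options: PipelineOptions | None = None,
) -> list[MetricsReport]:
    """Repeat the subject-specific train/evaluate cycle n_experiments times.

    Each experiment draws its own seed (derived from ``cfg.seed`` and the
    experiment index), re-balances, re-splits, re-standardizes, carves one
    stratified validation fold (fold index = experiment mod k_folds) out of
    the train windows for early stopping, trains a freshly initialized
    model, and evaluates once on the held-out repetitions. Aggregate
    mean +/- SD and the 95% CI are available via
    :func:`semgbench.evaluation.aggregate_reports`.
    """
    options = options or PipelineOptions()
    present = set(np.unique(rec.repetition)) - {0}
    needed = set(split.train_reps) | set(split.test_reps)
    if not needed <= present:
        raise ValueError(
            f"recording lacks repetitions {sorted(needed - present)} named by the split"
        )
    windows = segment_windows(rec)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(n_experiments) % (2**31 - 1)

    reports: list[MetricsReport] = []
    for exp, exp_seed in enumerate(map(int, seeds)):
        train_ws, test_ws = _preprocess_split(windows, split, options, seed=exp_seed)
        assert not set(np.unique(train_ws.repetitions)) & set(split.test_reps), (
            "held-out repetition leaked into the training windows"
        )
        min_class = min(train_ws.class_counts().values())
        if min_class < k_folds:
            raise ValueError(
                f"class with only {min_class} train windows cannot support "
                f"{k_folds}-fold stratification"
            )
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=exp_seed)
        folds = list(skf.split(train_ws.data, train_ws.labels))
        fit_idx, val_idx = folds[exp % k_folds]
        model = cfg.build_model(profile, seed=exp_seed)
        model, history = train(
            model,
            train_ws.subset(fit_idx),
            train_ws.subset(val_idx),
            replace(cfg, seed=exp_seed),
        )
        y_pred = model.predict(test_ws.data)
        report = confusion_and_metrics(test_ws.labels, y_pred, profile.n_classes)
        logger.info(
            "%s experiment %d/%d: test acc %.3f (best epoch %d/%d%s)",
            rec.subject_id, exp + 1, n_experiments, report.accuracy,
            history.best_epoch + 1, history.n_epochs,
            ", early stop" if history.stopped_early else "",
        )
        reports.append(report)
    return reports
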