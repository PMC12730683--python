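"""Preprocessing stack: standardization, companding, filtering, windowing.

The stages cover both device profiles end to end:

1. *Per-class standardization* — each channel is scaled to zero mean and
   unit variance within each gesture class, x' = (x - mu[c, j]) / sigma[c, j].
   Because the statistics are class-conditional they are fitted on training
   data only and then applied to test data (fit/transform split), so no test
   information leaks into the scaling.
2. *µ-law companding* — F(x) = sign(x) ln(1 + mu |x|) / ln(1 + mu) on
   [-1, 1], an odd, monotone logarithmic compressor (classic telephony
   constant mu = 255 by default) that tames large-amplitude bursts.
3. *Butterworth low-pass cascade* — the same signal filtered at orders
   1, 3 and 5 (zero-phase, unit DC gain), stacked into a 3-deep
   representation used by the DB3 pipeline.
4. *Class-pure sliding windows* — fixed windows of W samples with overlap O
   (stride W - O); a window is kept only if all its samples share one label
   and one repetition index.
5. *Class balancing* — seeded downsampling without replacement to the
   minimum class count, followed by a reshuffle.
6. *Repetition-based splits* — train/test partition by stimulus repetition
   index; the six canonical splits are in :data:`REPETITION_SPLITS` (split 5
   is refused by the validator because its train and test sets as tabulated
   share repetition 6).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .containers import Recording, WindowSet

logger = logging.getLogger(__name__)

__all__ = [
    "StandardizationParams",
    "standardize_per_class",
    "standardize_windows",
    "mu_law_normalize",
    "rescale_to_unit",
    "butterworth_stack",
    "segment_windows",
    "balance_classes",
    "SplitSpec",
    "REPETITION_SPLITS",
    "get_split",
    "split_by_repetition",
]


@dataclass
class StandardizationParams:
    """Per-(class, channel) mean and standard deviation.

    ``mu`` and ``sigma`` are (n_classes, n_channels). Population
    (n-denominator) standard deviation is used.
    """

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu and sigma must share shape")
        if not (np.all(np.isfinite(self.mu)) and np.all(np.isfinite(self.sigma))):
            raise ValueError("standardization parameters must be finite")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be nonnegative")


def _fit_params(
    values_by_class: dict[int, np.ndarray], n_classes: int, n_channels: int
) -> StandardizationParams:
    """Fit per-(class, channel) statistics from {class: (n_channels, n) arrays}."""
    mu = np.zeros((n_classes, n_channels))
    sigma = np.ones((n_classes, n_channels))
    for cls, vals in values_by_class.items():
        if vals.shape[1] < 2:
            raise ValueError(f"class {cls} has < 2 samples; cannot fit statistics")
        mu[cls] = vals.mean(axis=1)
        sigma[cls] = vals.std(axis=1)  # population sd
        zero = np.flatnonzero(sigma[cls] == 0)
        if zero.size:
            raise ValueError(
                f"degenerate standardization: sigma = 0 for class {cls}, "
                f"channel(s) {zero.tolist()}"
            )
    return StandardizationParams(mu=mu, sigma=sigma)


def standardize_per_class(
    rec: Recording, params: StandardizationParams | None = None
) -> tuple[Recording, StandardizationParams]:
    """Standardize each channel to zero mean / unit variance within each class.

    With ``params=None`` (fitting mode) the statistics are computed from this
    recording; otherwise the given parameters are applied (transform mode).
    """
    n_classes = rec.profile.n_classes
    if params is None:
        by_class = {
            int(c): rec.samples[:, rec.labels == c] for c in np.unique(rec.labels)
        }
        params = _fit_params(by_class, n_classes, rec.profile.n_channels)
    out = rec.samples.copy()
    for c in range(n_classes):
        mask = rec.labels == c
        if mask.any():
            out[:, mask] = (out[:, mask] - params.mu[c][:, None]) / params.sigma[c][:, None]
    if not np.all(np.isfinite(out)):
        raise ValueError("standardized output contains non-finite values")
    return rec.copy_with(samples=out), params


def standardize_windows(
    ws: WindowSet, params: StandardizationParams | None = None
) -> tuple[WindowSet, StandardizationParams]:
    """Window-level variant of :func:`standardize_per_class`.

    Fitting pools all samples of all windows of a class; used by the training
    protocol to fit on train windows and transform test windows.
    """
    n_classes = ws.profile.n_classes
    if params is None:
        by_class = {}
        for c in np.unique(ws.labels):
            wins = ws.data[ws.labels == c]  # (n, ch, W)
            by_class[int(c)] = wins.transpose(1, 0, 2).reshape(ws.profile.n_channels, -1)
        params = _fit_params(by_class, n_classes, ws.profile.n_channels)
    out = ws.data.copy()
    for c in range(n_classes):
        mask = ws.labels == c
        if mask.any():
            out[mask] = (out[mask] - params.mu[c][None, :, None]) / params.sigma[c][None, :, None]
    return (
        WindowSet(out, ws.labels, ws.repetitions, ws.subject_id, ws.profile),
        params,
    )


def standardize_windows_global(
    ws: WindowSet, params: tuple[np.ndarray, np.ndarray] | None = None
) -> tuple[WindowSet, tuple[np.ndarray, np.ndarray]]:
    """Class-agnostic per-channel standardization of a window set.

    Fits per-channel mean/SD over all windows pooled across classes (or
    applies given ``(mu, sigma)``), so it can be applied to unlabeled test
    data and preserves between-class amplitude differences. This is the
    scaling the training protocol uses; the class-conditional variant
    (:func:`standardize_windows`) needs labels at transform time.
    """
    if params is None:
        flat = ws.data.transpose(1, 0, 2).reshape(ws.profile.n_channels, -1)
        mu = flat.mean(axis=1)
        sigma = flat.std(axis=1)
        if np.any(sigma == 0):
            raise ValueError(
                f"degenerate channel(s) {np.flatnonzero(sigma == 0).tolist()}: sigma = 0"
            )
        params = (mu, sigma)
    mu, sigma = params
    out = (ws.data - mu[None, :, None]) / sigma[None, :, None]
    return WindowSet(out, ws.labels, ws.repetitions, ws.subject_id, ws.profile), params


def mu_law_normalize(x: np.ndarray, mu: float = 255.0) -> np.ndarray:
    """µ-law companding F(x) = sign(x) ln(1 + mu |x|) / ln(1 + mu) on [-1, 1].

    Odd, strictly monotone, fixes 0 and ±1. The caller must rescale to
    |x| <= 1 first (see :func:`rescale_to_unit`).
    """
    x = np.asarray(x, dtype=np.float64)
    if mu <= 0:
        raise ValueError(f"mu must be positive, got {mu}")
    if np.any(np.abs(x) > 1 + 1e-12):
        raise ValueError("mu-law input must satisfy |x| <= 1; rescale first")
    return np.sign(x) * np.log1p(mu * np.abs(x)) / np.log1p(mu)


def rescale_to_unit(x: np.ndarray, scale: np.ndarray | None = None, axis=None):
    """Divide by max |x| (per ``axis`` slice or globally) so |x| <= 1.

    Returns (rescaled, scale); pass a training-set ``scale`` to transform
    test data consistently. Values beyond the training scale are clipped to
    ±1 so the µ-law domain holds.
    """
    x = np.asarray(x, dtype=np.float64)
    if scale is None:
        scale = np.max(np.abs(x), axis=axis, keepdims=axis is not None)
        scale = np.where(scale == 0, 1.0, scale)
    return np.clip(x / scale, -1.0, 1.0), scale


def butterworth_stack(
    rec: Recording,
    orders: tuple[int, ...] = (1, 3, 5),
    cutoff_hz: float | None = None,
) -> np.ndarray:
    """Low-pass the signal once per filter order and stack the outputs.

    Returns (len(orders), n_channels, T). Each copy is zero-phase
    (forward-backward) filtered with unit DC gain; higher orders attenuate
    above-cutoff content more steeply. Default cutoff is fs/4.
    """
    fs = rec.profile.fs
    if cutoff_hz is None:
        cutoff_hz = fs / 4.0
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError(f"cutoff_hz must lie in (0, fs/2) = (0, {fs / 2}), got {cutoff_hz}")
    out = np.empty((len(orders), rec.samples.shape[0], rec.samples.shape[1]))
    for i, order in enumerate(orders):
        b, a = _sig.butter(order, cutoff_hz, btype="low", fs=fs)
        out[i] = _sig.filtfilt(b, a, rec.samples, axis=1)
    return out


def segment_windows(rec: Recording, W: int | None = None, O: int | None = None) -> WindowSet:
    """Cut class-pure sliding windows of length W with overlap O.

    Window k starts at k (W - O); a window is kept iff all W labels are equal
    and the repetition index is constant within the window. The kept window
    inherits that label, repetition and the subject id. W > T yields an
    empty set with a warning rather than an error.
    """
    W = rec.profile.window_len if W is None else W
    O = rec.profile.overlap if O is None else O
    if not 0 <= O < W:
        raise ValueError(f"require 0 <= O < W, got O={O}, W={W}")
    T = rec.n_samples
    if W > T:
        logger.warning(
            "%s: window length %d exceeds recording length %d; no windows",
            rec.subject_id, W, T,
        )
        return WindowSet(
            data=np.empty((0, rec.profile.n_channels, W)),
            labels=np.empty(0, dtype=np.int64),
            repetitions=np.empty(0, dtype=np.int64),
            subject_id=rec.subject_id,
            profile=rec.profile,
        )
    stride = W - O
    # windows are aligned within each maximal (label, repetition) run, so a
    # run of length L >= W yields exactly floor((L - W) / stride) + 1 windows
    change = np.flatnonzero(
        (np.diff(rec.labels) != 0) | (np.diff(rec.repetition) != 0)
    )
    run_bounds = np.concatenate([[0], change + 1, [T]])
    data, labels, reps = [], [], []
    for lo, hi in zip(run_bounds[:-1], run_bounds[1:]):
        for s in range(lo, hi - W + 1, stride):
            data.append(rec.samples[:, s : s + W])
            labels.append(rec.labels[s])
            reps.append(rec.repetition[s])
    return WindowSet(
        data=np.asarray(data) if data else np.empty((0, rec.profile.n_channels, W)),
        labels=np.asarray(labels, dtype=np.int64),
        repetitions=np.asarray(reps, dtype=np.int64),
        subject_id=rec.subject_id,
        profile=rec.profile,
    )


def balance_classes(ws: WindowSet, seed: int = 0) -> WindowSet:
    """Downsample every class (without replacement) to the minimum class count.

    The selection and the final reshuffle are driven by ``seed``, so two runs
    with the same seed return identical window order.
    """
    counts = ws.class_counts()
    missing = [c for c in range(ws.profile.n_classes) if counts.get(c, 0) == 0]
    if missing:
        raise ValueError(f"cannot balance: class(es) {missing} have zero windows")
    rng = np.random.default_rng(seed)
    n_min = min(counts.values())
    chosen = []
    for c in sorted(counts):
        idx = np.flatnonzero(ws.labels == c)
        chosen.append(rng.choice(idx, size=n_min, replace=False))
    idx = np.concatenate(chosen)
    rng.shuffle(idx)
    return ws.subset(idx)


@dataclass(frozen=True)
class SplitSpec:
    """Train/test repetition sets; validated disjoint."""

    train_reps: frozenset[int]
    test_reps: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "train_reps", frozenset(self.train_reps))
        object.__setattr__(self, "test_reps", frozenset(self.test_reps))
        overlap = self.train_reps & self.test_reps
        if overlap:
            raise ValueError(
                f"train and test repetition sets overlap on {sorted(overlap)}; "
                "a repetition cannot appear on both sides of the split"
            )
        if not self.train_reps or not self.test_reps:
            raise ValueError("train and test repetition sets must be non-empty")


#: The six canonical repetition splits, keyed by split id. Split 5 is kept
#: verbatim from the benchmark's legacy tabulation — repetition 6 appears in
#: both train and test — and the SplitSpec validator refuses it (presumably a
#: transcription error).
REPETITION_SPLITS: dict[int, tuple[tuple[int, ...], tuple[int, ...]]] = {
    1: ((1, 3, 4, 6), (2, 5)),
    2: ((1, 4, 5, 6), (2, 3)),
    3: ((1, 2, 3, 5), (4, 6)),
    4: ((1, 2, 4, 6), (3, 5)),
    5: ((2, 4, 5, 6), (1, 6)),
    6: ((2, 3, 5, 6), (1, 4)),
}


def get_split(split_id: int) -> SplitSpec:
    """Return the validated SplitSpec for a canonical split id (1-6)."""
    if split_id not in REPETITION_SPLITS:
        raise KeyError(f"unknown split id {split_id}; known: {sorted(REPETITION_SPLITS)}")
    train, test = REPETITION_SPLITS[split_id]
    return SplitSpec(train_reps=frozenset(train), test_reps=frozenset(test))


def split_by_repetition(ws: WindowSet, split: SplitSpec) -> tuple[WindowSet, WindowSet]:
    """Partition windows by repetition index into (train, test).

    Windows whose repetition is in neither set are discarded with a logged
    count.
    """
    train_mask = np.isin(ws.repetitions, list(split.train_reps))
    test_mask = np.isin(ws.repetitions, list(split.test_reps))
    discarded = int((~(train_mask | test_mask)).sum())
    if discarded:
        logger.info(
            "%s: %d windows outside split repetitions discarded",
            ws.subject_id, discarded,
        )
    return ws.subset(np.flatnonzero(train_mask)), ws.subset(np.flatnonzero(test_mask))
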