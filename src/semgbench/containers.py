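"""Core data containers shared by every pipeline stage.

A :class:`DatasetProfile` freezes the acquisition geometry (channel count,
sampling rate) together with the segmentation constants (window length and
overlap) of the two device families the benchmark emulates: the 8-channel
200 Hz Myo armband and a 12-channel 2 kHz NinaPro-DB3-style montage.
:class:`Recording` carries a continuous multichannel signal with per-sample
gesture labels and repetition indices; :class:`WindowSet` holds the
class-pure segmented windows that the classifiers consume.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: Study gesture vocabulary, class index order 0..5.
GESTURE_CODES = ("RE", "AP", "PI", "PO", "MO", "AT")
N_CLASSES = len(GESTURE_CODES)


@dataclass(frozen=True)
class DatasetProfile:
    """Acquisition and segmentation constants for one recording dialect.

    Parameters
    ----------
    name : str
        ``"myo"`` or ``"db3"``.
    n_channels : int
        Electrode channel count (8 for Myo, 12 for DB3).
    fs : float
        Sampling rate in Hz.
    window_len : int
        Sliding-window length W in samples.
    overlap : int
        Overlap O between consecutive windows, in samples (stride = W - O).
    n_classes : int
        Number of gesture classes including rest.
    """

    name: str
    n_channels: int
    fs: float
    window_len: int
    overlap: int
    n_classes: int = N_CLASSES

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError(f"n_channels must be >= 1, got {self.n_channels}")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not 0 <= self.overlap < self.window_len:
            raise ValueError(
                f"require 0 <= overlap < window_len, got overlap={self.overlap}, "
                f"window_len={self.window_len}"
            )

    @property
    def stride(self) -> int:
        return self.window_len - self.overlap

    @property
    def input_shape(self) -> tuple[int, int, int]:
        """Model input shape (channels, window, depth-1) for this profile."""
        return (self.n_channels, self.window_len, 1)


#: Myo armband: 8 dry electrodes at 200 Hz, 30-sample (~150 ms) windows with
#: 15-sample (50%) overlap.
MYO = DatasetProfile(name="myo", n_channels=8, fs=200.0, window_len=30, overlap=15)

#: NinaPro-DB3-style montage: 12 channels at 2 kHz, 50-sample (~25 ms)
#: windows with 15-sample overlap.
DB3 = DatasetProfile(name="db3", n_channels=12, fs=2000.0, window_len=50, overlap=15)

PROFILES = {"myo": MYO, "db3": DB3}


def get_profile(name: str) -> DatasetProfile:
    try:
        return PROFILES[name]
    except KeyError:
        raise KeyError(f"unknown profile {name!r}; known: {sorted(PROFILES)}") from None


@dataclass
class Recording:
    """A continuous multichannel recording with per-sample annotations.

    ``samples`` is (n_channels, T); ``labels`` and ``repetition`` are length-T
    integer streams. Repetition index 0 marks samples outside any stimulus.
    """

    subject_id: str
    profile: DatasetProfile
    samples: np.ndarray
    labels: np.ndarray
    repetition: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.repetition = np.asarray(self.repetition, dtype=np.int64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (n_channels, T)")
        n_ch, T = self.samples.shape
        if n_ch != self.profile.n_channels:
            raise ValueError(
                f"recording has {n_ch} channels but profile "
                f"{self.profile.name!r} expects {self.profile.n_channels}"
            )
        if self.labels.shape != (T,) or self.repetition.shape != (T,):
            raise ValueError("labels and repetition must both have length T")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def copy_with(self, **kw) -> "Recording":
        return replace(self, **kw)


@dataclass
class WindowSet:
    """Segmented, class-pure windows ready for model consumption.

    ``data`` is (n_windows, n_channels, window_len); ``labels`` and
    ``repetitions`` are per-window integers. ``subject_id`` tags provenance so
    the training protocol can assert that held-out repetitions never reach
    the optimizer.
    """

    data: np.ndarray
    labels: np.ndarray
    repetitions: np.ndarray
    subject_id: str
    profile: DatasetProfile

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.repetitions = np.asarray(self.repetitions, dtype=np.int64)
        n = len(self.data)
        if self.labels.shape != (n,) or self.repetitions.shape != (n,):
            raise ValueError("labels and repetitions must match n_windows")

    def __len__(self) -> int:
        return len(self.data)

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def subset(self, idx: np.ndarray) -> "WindowSet":
        return WindowSet(
            data=self.data[idx],
            labels=self.labels[idx],
            repetitions=self.repetitions[idx],
            subject_id=self.subject_id,
            profile=self.profile,
        )
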