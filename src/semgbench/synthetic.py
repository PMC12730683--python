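"""Synthetic sEMG-like recording generator.

Surface EMG is well approximated as amplitude-modulated colored noise: the
interference pattern of many motor-unit action potentials looks Gaussian at
the electrode, and gesture intent expresses itself mainly through the RMS
envelope per channel. The generator therefore draws zero-mean Gaussian
noise, shapes it with a low-pass Butterworth filter (cutoff fs/4), and
modulates its amplitude with a trapezoidal activation envelope per gesture
segment so that the steady-state per-channel RMS during a gesture ``g``
segment equals ``baseline_rms * (1 + snr * gain[g, ch])``. Rest segments
carry gain 0 on every channel and sit at baseline RMS.

Each subject owns a (n_classes x n_channels) gain matrix; a cohort draws
per-subject gains around a shared template with a configurable multiplicative
spread, emulating inter-subject variability. A "degenerate" subject mode
collapses all gesture gain rows to one class-independent row, mimicking a
participant without residual musculature whose signals carry no class
information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .containers import DatasetProfile, Recording

__all__ = ["SubjectSpec", "generate_subject", "generate_cohort", "template_gains"]

#: Fraction of each gesture segment spent ramping up / down (trapezoid).
_RAMP_FRACTION = 0.1


@dataclass
class SubjectSpec:
    """Generative parameters for one synthetic subject.

    ``gain`` is (n_classes, n_channels) of nonnegative RMS multipliers; row 0
    (rest) must be all zeros so rest sits at baseline. ``snr`` is the ratio
    of gesture-driven RMS excess to baseline RMS. Durations are seconds per
    repetition.
    """

    subject_id: str
    gain: np.ndarray
    baseline_rms: float = 1.0
    snr: float = 1.0
    n_repetitions: int = 6
    gesture_duration_s: float = 5.0
    rest_duration_s: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=np.float64)
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("gain matrix contains non-finite values")
        if np.any(self.gain < 0):
            raise ValueError("gain multipliers must be nonnegative")
        if self.baseline_rms <= 0:
            raise ValueError("baseline_rms must be positive")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if self.n_repetitions < 2:
            raise ValueError(
                "n_repetitions must be >= 2 (a train/test repetition split "
                "needs at least two repetitions)"
            )
        if np.any(self.gain[0] != 0):
            raise ValueError("rest gain row (class 0) must be all zeros")


def template_gains(
    n_classes: int, n_channels: int, rng: np.random.Generator
) -> np.ndarray:
    """A shared cohort gain template with distinct per-class channel patterns.

    Each gesture class activates a different subset of channels (a smooth
    bump centred on a class-specific channel), giving classes separable RMS
    signatures. Rest (row 0) is all zeros.
    """
    gains = np.zeros((n_classes, n_channels))
    ch = np.arange(n_channels)
    for c in range(1, n_classes):
        centre = (c - 1) * n_channels / max(n_classes - 1, 1)
        width = max(n_channels / 4.0, 1.0)
        bump = np.exp(-0.5 * ((ch - centre) / width) ** 2)
        gains[c] = 0.3 + bump  # floor keeps every channel mildly active
    return gains


def _colored_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS zero-mean Gaussian noise low-passed at fs/4."""
    white = rng.standard_normal(n)
    b, a = _sig.butter(4, 0.5)  # fs/4 relative to Nyquist fs/2
    x = _sig.lfilter(b, a, white)
    x -= x.mean()
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _trapezoid(n: int) -> np.ndarray:
    """Trapezoidal activation envelope in [0, 1] over n samples."""
    ramp = max(int(round(_RAMP_FRACTION * n)), 1)
    env = np.ones(n)
    env[:ramp] = np.linspace(0.0, 1.0, ramp, endpoint=False)
    env[n - ramp :] = np.linspace(1.0, 0.0, ramp + 1)[1:]
    return env


def generate_subject(spec: SubjectSpec, profile: DatasetProfile) -> Recording:
    """Generate one subject's recording.

    The timeline per repetition r is: one rest run (class 0, repetition r)
    followed by one run per gesture class 1..n_classes-1 (class g,
    repetition r), so every requested (class, repetition) pair appears as
    exactly one contiguous run. Identical spec and seed produce bit-identical
    output.
    """
    n_classes, n_channels = spec.gain.shape
    if n_classes != profile.n_classes or n_channels != profile.n_channels:
        raise ValueError(
            f"gain matrix shape {spec.gain.shape} does not match profile "
            f"({profile.n_classes} classes, {profile.n_channels} channels)"
        )
    rng = np.random.default_rng(spec.seed)
    n_gest = int(round(spec.gesture_duration_s * profile.fs))
    n_rest = int(round(spec.rest_duration_s * profile.fs))
    if min(n_gest, n_rest) < profile.window_len:
        raise ValueError("segment durations shorter than one window")

    chunks, lab_chunks, rep_chunks = [], [], []
    for rep in range(1, spec.n_repetitions + 1):
        for cls in range(n_classes):
            n = n_rest if cls == 0 else n_gest
            env = _trapezoid(n)
            seg = np.empty((n_channels, n))
            for ch in range(n_channels):
                noise = _colored_noise(n, profile.fs, rng)
                # target RMS: baseline * (1 + snr * gain) at full activation
                target = spec.baseline_rms * (1.0 + spec.snr * spec.gain[cls, ch])
                # baseline floor plus envelope-modulated gesture excess
                amp = spec.baseline_rms + (target - spec.baseline_rms) * env
                seg[ch] = noise * amp
            chunks.append(seg)
            lab_chunks.append(np.full(n, cls, dtype=np.int64))
            rep_chunks.append(np.full(n, rep, dtype=np.int64))

    return Recording(
        subject_id=spec.subject_id,
        profile=profile,
        samples=np.concatenate(chunks, axis=1),
        labels=np.concatenate(lab_chunks),
        repetition=np.concatenate(rep_chunks),
    )


def generate_cohort(
    n_subjects: int,
    profile: DatasetProfile,
    variability: float = 0.15,
    master_seed: int = 0,
    degenerate_ids: set[str] | None = None,
    snr: float = 1.0,
    baseline_rms: float = 1.0,
    n_repetitions: int = 6,
    gesture_duration_s: float = 5.0,
    rest_duration_s: float = 3.0,
) -> list[Recording]:
    """Generate a cohort of subjects around a shared gain template.

    Subject ids are ``"S1"``.. ``"S<n>"``. Per-subject gesture gains are the
    template multiplied elementwise by lognormal factors with multiplicative
    spread ``variability`` (``variability=0`` reproduces the template
    exactly). Subjects named in ``degenerate_ids`` receive class-independent
    gains: every gesture row equals the template's mean gesture row, so their
    signals carry no class information (the "no residual musculature" case).
    The whole cohort is reproducible from ``master_seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ids = [f"S{i + 1}" for i in range(n_subjects)]
    degenerate_ids = set(degenerate_ids or ())
    unknown = degenerate_ids - set(ids)
    if unknown:
        raise ValueError(f"degenerate_ids {sorted(unknown)} not among generated ids {ids}")

    master = np.random.default_rng(master_seed)
    template = template_gains(profile.n_classes, profile.n_channels, master)
    subject_seeds = master.integers(0, 2**31 - 1, size=n_subjects)

    recordings = []
    for sid, sub_seed in zip(ids, subject_seeds):
        rng = np.random.default_rng(sub_seed)
        if variability > 0:
            factors = np.exp(variability * rng.standard_normal(template.shape))
        else:
            factors = np.ones_like(template)
        gains = template * factors
        gains[0] = 0.0
        if sid in degenerate_ids:
            flat = gains[1:].mean(axis=0)
            gains[1:] = flat  # identical rows: no class information
        spec = SubjectSpec(
            subject_id=sid,
            gain=gains,
            baseline_rms=baseline_rms,
            snr=snr,
            n_repetitions=n_repetitions,
            gesture_duration_s=gesture_duration_s,
            rest_duration_s=rest_duration_s,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        recordings.append(generate_subject(spec, profile))
    return recordings
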