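import numpy as np
import pytest

from semgbench.containers import MYO, DatasetProfile, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(
    labels, repetitions, n_channels=8, profile=None, seed=0, scale_by_label=False
):
    """Build a recording with given per-sample label/repetition streams.

    With ``scale_by_label`` the noise amplitude is (1 + label), giving
    classes trivially separable RMS structure.
    """
    labels = np.asarray(labels, dtype=np.int64)
    repetitions = np.asarray(repetitions, dtype=np.int64)
    profile = profile or MYO
    r = np.random.default_rng(seed)
    samples = r.standard_normal((profile.n_channels, len(labels)))
    if scale_by_label:
        samples *= 1.0 + labels[None, :]
    return Recording(
        subject_id="T1",
        profile=profile,
        samples=samples,
        labels=labels,
        repetition=repetitions,
    )


@pytest.fixture
def tiny_profile():
    """A short-window profile for fast windowing tests."""
    return DatasetProfile(name="myo", n_channels=8, fs=200.0, window_len=10, overlap=5)
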