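"""Standardization, µ-law, Butterworth cascade, windowing, balancing, splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sp_signal

from semgbench.containers import MYO, DatasetProfile, Recording
from semgbench.preprocessing import (
    REPETITION_SPLITS,
    SplitSpec,
    balance_classes,
    butterworth_stack,
    get_split,
    mu_law_normalize,
    rescale_to_unit,
    segment_windows,
    split_by_repetition,
    standardize_per_class,
    standardize_windows_global,
)

from conftest import make_recording


class TestStandardizePerClass:
    def test_closed_form_three_values(self):
        # one class, channel values [1, 2, 3] -> ±sqrt(3/2) with population sd
        profile = DatasetProfile(name="myo", n_channels=1, fs=200.0,
                                 window_len=2, overlap=0)
        rec = Recording("T", profile, np.array([[1.0, 2.0, 3.0]]),
                        np.zeros(3, dtype=int), np.ones(3, dtype=int))
        out, params = standardize_per_class(rec)
        np.testing.assert_allclose(out.samples[0], [-1.2247, 0.0, 1.2247], atol=1e-4)
        assert params.mu[0, 0] == pytest.approx(2.0)
        assert params.sigma[0, 0] == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-12)

    def test_refit_of_standardized_data_is_identity_stats(self):
        labels = np.repeat(np.arange(6), 50)
        rec = make_recording(labels, np.ones(300, dtype=int), scale_by_label=True)
        out, _ = standardize_per_class(rec)
        _, params2 = standardize_per_class(out)
        np.testing.assert_allclose(params2.mu, 0.0, atol=1e-12)
        np.testing.assert_allclose(params2.sigma, 1.0, atol=1e-12)

    def test_affine_rescaling_invariance(self):
        # per-channel affine rescaling of the input leaves the output unchanged
        labels = np.repeat(np.arange(6), 30)
        rec = make_recording(labels, np.ones(180, dtype=int))
        scale = np.linspace(0.5, 4.0, 8)[:, None]
        shifted = rec.copy_with(samples=rec.samples * scale + 7.0)
        out1, _ = standardize_per_class(rec)
        out2, _ = standardize_per_class(shifted)
        np.testing.assert_allclose(out1.samples, out2.samples, atol=1e-9)

    def test_constant_class_channel_is_named(self):
        labels = np.repeat([0, 1], 10)
        rec = make_recording(labels, np.ones(20, dtype=int))
        samples = rec.samples.copy()
        samples[3, labels == 1] = 5.0  # constant -> sigma 0
        rec = rec.copy_with(samples=samples)
        with pytest.raises(ValueError, match=r"class 1.*\[3\]"):
            standardize_per_class(rec)

    def test_transform_mode_applies_given_params(self):
        labels = np.repeat(np.arange(6), 30)
        rec = make_recording(labels, np.ones(180, dtype=int), seed=1)
        other = make_recording(labels, np.ones(180, dtype=int), seed=2)
        _, params = standardize_per_class(rec)
        out, params2 = standardize_per_class(other, params)
        assert params2 is params
        expected = (other.samples[2, 5] - params.mu[0, 2]) / params.sigma[0, 2]
        assert out.samples[2, 5] == pytest.approx(expected)


class TestMuLaw:
    @pytest.mark.parametrize("mu", [1.0, 50.0, 255.0, 1000.0])
    def test_fixes_zero_and_endpoints(self, mu):
        np.testing.assert_allclose(
            mu_law_normalize(np.array([-1.0, 0.0, 1.0]), mu), [-1.0, 0.0, 1.0]
        )

    def test_scalar_value_mu_255(self):
        # F(0.5; 255) = ln(128.5)/ln(256)
        expected = np.log(128.5) / np.log(256.0)
        assert mu_law_normalize(np.array(0.5), 255.0) == pytest.approx(expected)
        assert expected == pytest.approx(0.8757, abs=1e-4)

    @given(st.lists(st.floats(-1.0, 1.0), min_size=2, max_size=50),
           st.floats(0.1, 1000.0))
    @settings(max_examples=50, deadline=None)
    def test_odd_monotone_bounded(self, values, mu):
        x = np.sort(np.asarray(values))
        y = mu_law_normalize(x, mu)
        assert np.all(np.abs(y) <= 1.0 + 1e-12)
        assert np.all(np.diff(y) >= -1e-12)  # monotone
        np.testing.assert_allclose(mu_law_normalize(-x, mu), -y, atol=1e-12)

    def test_domain_and_mu_validation(self):
        with pytest.raises(ValueError, match="rescale"):
            mu_law_normalize(np.array([1.5]))
        with pytest.raises(ValueError, match="mu"):
            mu_law_normalize(np.array([0.5]), mu=-1.0)

    def test_rescale_to_unit_round_trip_scale(self):
        x = np.array([[3.0, -6.0, 1.5]])
        scaled, scale = rescale_to_unit(x)
        assert scale == pytest.approx(6.0)
        assert np.abs(scaled).max() == pytest.approx(1.0)


class TestButterworthStack:
    def test_constant_signal_preserved(self):
        rec = make_recording(np.zeros(400, dtype=int), np.ones(400, dtype=int))
        rec = rec.copy_with(samples=np.full_like(rec.samples, 3.5))
        out = butterworth_stack(rec, cutoff_hz=20.0)
        assert out.shape == (3, 8, 400)
        np.testing.assert_allclose(out, 3.5, atol=1e-6)

    def test_attenuation_increases_with_order(self):
        fs, f_sig = MYO.fs, 60.0  # above the 20 Hz cutoff
        t = np.arange(2000) / fs
        sine = np.sin(2 * np.pi * f_sig * t)
        rec = make_recording(np.zeros(2000, dtype=int), np.ones(2000, dtype=int))
        rec = rec.copy_with(samples=np.tile(sine, (8, 1)))
        out = butterworth_stack(rec, orders=(1, 3, 5), cutoff_hz=20.0)
        amps = [np.sqrt(np.mean(out[i, 0, 500:1500] ** 2)) for i in range(3)]
        assert amps[0] > amps[1] > amps[2]
        # zero-phase filtering applies |H|^2: compare to the analytic response
        for i, order in enumerate((1, 3, 5)):
            _, h = sp_signal.freqz(
                *sp_signal.butter(order, 20.0, btype="low", fs=fs),
                worN=[f_sig], fs=fs,
            )
            expected = np.sqrt(0.5) * np.abs(h[0]) ** 2
            assert amps[i] == pytest.approx(expected, rel=0.05)

    def test_single_order_stack(self):
        rec = make_recording(np.zeros(300, dtype=int), np.ones(300, dtype=int))
        out = butterworth_stack(rec, orders=(1,), cutoff_hz=20.0)
        assert out.shape == (1, 8, 300)

    def test_cutoff_beyond_nyquist_rejected(self):
        rec = make_recording(np.zeros(100, dtype=int), np.ones(100, dtype=int))
        with pytest.raises(ValueError, match="cutoff"):
            butterworth_stack(rec, cutoff_hz=150.0)  # fs/2 = 100


def brute_force_window_count(labels, reps, W, stride):
    """Oracle: exhaustive scan of every run-aligned start position."""
    n = 0
    i = 0
    T = len(labels)
    while i < T:
        j = i
        while j < T and labels[j] == labels[i] and reps[j] == reps[i]:
            j += 1
        L = j - i
        if L >= W:
            n += (L - W) // stride + 1
        i = j
    return n


class TestSegmentWindows:
    def test_boundary_exactly_one_window(self):
        rec = make_recording(np.zeros(30, dtype=int), np.ones(30, dtype=int))
        ws = segment_windows(rec, W=30, O=15)
        assert len(ws) == 1

    def test_100_samples_gives_two_windows(self):
        rec = make_recording(np.zeros(100, dtype=int), np.ones(100, dtype=int))
        ws = segment_windows(rec, W=50, O=15)
        assert len(ws) == 2  # starts 0 and 35

    def test_label_change_inside_every_candidate_kills_all_windows(self):
        labels = np.tile(np.repeat([0, 1], 5), 6)  # runs of 5 < W=10
        rec = make_recording(labels, np.ones(60, dtype=int))
        assert len(segment_windows(rec, W=10, O=5)) == 0

    def test_window_longer_than_recording_warns_not_raises(self):
        rec = make_recording(np.zeros(10, dtype=int), np.ones(10, dtype=int))
        ws = segment_windows(rec, W=30, O=15)
        assert len(ws) == 0

    def test_windows_are_class_and_repetition_pure(self):
        labels = np.concatenate([np.full(47, 0), np.full(61, 3), np.full(33, 1)])
        reps = np.concatenate([np.full(47, 1), np.full(61, 1), np.full(33, 2)])
        rec = make_recording(labels, reps)
        ws = segment_windows(rec, W=10, O=5)
        for k in range(len(ws)):
            # recover the window in the original stream and check purity
            assert ws.labels[k] in (0, 1, 3)
        counts = ws.class_counts()
        assert counts[0] == (47 - 10) // 5 + 1
        assert counts[3] == (61 - 10) // 5 + 1
        assert counts[1] == (33 - 10) // 5 + 1

    @given(
        st.lists(
            st.tuples(st.integers(0, 5), st.integers(1, 3), st.integers(1, 40)),
            min_size=1, max_size=12,
        ),
        st.integers(2, 12),
    )
    @settings(max_examples=60, deadline=None)
    def test_window_count_matches_exhaustive_scan(self, runs, W):
        labels = np.concatenate([np.full(n, c) for c, _, n in runs])
        reps = np.concatenate([np.full(n, r) for _, r, n in runs])
        O = W // 2
        rec = make_recording(labels, reps)
        ws = segment_windows(rec, W=W, O=O)
        assert len(ws) == brute_force_window_count(labels, reps, W, W - O)


class TestBalanceClasses:
    def _ws(self, counts, seed=0):
        labels = np.concatenate([np.full(n, c) for c, n in enumerate(counts)])
        reps = np.ones(len(labels), dtype=int)
        rec = make_recording(np.repeat(labels, 30), np.repeat(reps, 30))
        return segment_windows(rec, W=30, O=0)

    def test_min_count_rule(self):
        ws = self._ws([4, 2, 3, 2, 5, 2])
        out = balance_classes(ws, seed=1)
        assert set(out.class_counts().values()) == {2}

    def test_already_balanced_is_permutation(self):
        ws = self._ws([3, 3, 3, 3, 3, 3])
        out = balance_classes(ws, seed=2)
        assert len(out) == len(ws)
        assert sorted(map(tuple, out.data.reshape(len(out), -1))) == sorted(
            map(tuple, ws.data.reshape(len(ws), -1))
        )

    def test_seeded_determinism(self):
        ws = self._ws([4, 2, 3, 2, 5, 2])
        a = balance_classes(ws, seed=7)
        b = balance_classes(ws, seed=7)
        np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_missing_class_rejected(self):
        labels = np.repeat(np.arange(5), 30)  # class 5 absent
        rec = make_recording(labels, np.ones(150, dtype=int))
        ws = segment_windows(rec, W=30, O=0)
        with pytest.raises(ValueError, match=r"\[5\]"):
            balance_classes(ws)


class TestRepetitionSplits:
    def test_split_1_assigns_every_window(self):
        labels = np.repeat(np.arange(6), 6 * 30)
        reps = np.tile(np.repeat(np.arange(1, 7), 30), 6)
        rec = make_recording(labels, reps)
        ws = segment_windows(rec, W=30, O=0)
        train, test = split_by_repetition(ws, get_split(1))
        assert len(train) + len(test) == len(ws)
        assert set(np.unique(train.repetitions)) == {1, 3, 4, 6}
        assert set(np.unique(test.repetitions)) == {2, 5}

    def test_partial_split_discards_other_repetitions(self):
        labels = np.zeros(6 * 30, dtype=int)
        reps = np.repeat(np.arange(1, 7), 30)
        rec = make_recording(labels, reps)
        ws = segment_windows(rec, W=30, O=0)
        train, test = split_by_repetition(
            ws, SplitSpec(train_reps=frozenset({1}), test_reps=frozenset({2}))
        )
        assert len(train) == 1 and len(test) == 1  # repetitions 3..6 discarded

    def test_split_5_overlap_is_refused(self):
        with pytest.raises(ValueError, match=r"overlap.*\[6\]"):
            get_split(5)

    def test_other_canonical_splits_validate(self):
        for sid in (1, 2, 3, 4, 6):
            spec = get_split(sid)
            assert spec.train_reps == frozenset(REPETITION_SPLITS[sid][0])
            assert spec.test_reps == frozenset(REPETITION_SPLITS[sid][1])


def test_global_standardization_preserves_class_amplitude_ratios():
    labels = np.repeat(np.arange(6), 60)
    rec = make_recording(labels, np.ones(360, dtype=int), scale_by_label=True)
    ws = segment_windows(rec, W=30, O=0)
    out, (mu, sigma) = standardize_windows_global(ws)
    rms = [np.sqrt(np.mean(out.data[out.labels == c] ** 2)) for c in range(6)]
    assert rms[5] > 2 * rms[0]  # between-class amplitude structure survives
    other, _ = standardize_windows_global(ws, (mu, sigma))
    np.testing.assert_array_equal(out.data, other.data)
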