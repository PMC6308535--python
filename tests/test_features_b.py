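"""Biomechanics-derived features: zero crossings, peaks, integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from harsel import features_b
from harsel.features_b import (FEATSET_B_NAMES, PeakEvent, extract_featset_b,
                               integrate, peak_statistics, peaks,
                               zero_crossings)

from conftest import make_window

FS = 80.0
N = 400
T = np.arange(N) / FS


def test_hand_enumerated_sign_changes():
    zc = zero_crossings(np.array([1.0, 1.0, -1.0, -1.0, 1.0]), remove_mean=False)
    np.testing.assert_array_equal(zc, [2, 4])


def test_constant_signal_has_no_crossings_after_mean_removal():
    assert zero_crossings(np.full(10, 5.0)).size == 0


def test_exact_zeros_inherit_previous_sign():
    zc = zero_crossings(np.array([1.0, 0.0, 1.0, -1.0]), remove_mean=False)
    np.testing.assert_array_equal(zc, [3])


def test_one_hertz_sine_has_nine_interior_crossings():
    x = np.sin(2 * np.pi * 1.0 * T)
    # brute-force count on the sampled grid
    s = np.sign(x[np.abs(x) > 1e-12])
    brute = int(np.sum(s[1:] != s[:-1]))
    got = zero_crossings(x).size
    assert got == brute == 9


def test_sine_peaks_have_half_period_durations():
    x = np.sin(2 * np.pi * 1.0 * T)
    ev = peaks(x, FS)
    pos = [e for e in ev if e.polarity == "positive"]
    neg = [e for e in ev if e.polarity == "negative"]
    assert len(pos) == len(neg) == 4
    for e in ev:
        assert e.duration == pytest.approx(0.5, abs=1.5 / FS)
        assert e.time_to_peak == pytest.approx(0.25, abs=1.5 / FS)
        assert abs(e.amplitude) == pytest.approx(1.0, abs=0.01)


def test_single_segment_amplitude_and_time_to_peak():
    # one interior positive segment between two crossings
    x = np.array([-1.0, 0.1, 0.5, 0.2, -1.0, 1.0])
    ev = peaks(x, fs=1.0, remove_mean=False)
    seg = [e for e in ev if e.polarity == "positive"][0]
    assert seg.amplitude == pytest.approx(0.5)
    assert seg.time_to_peak == pytest.approx(1.0)  # middle sample of segment


def test_mirrored_signal_swaps_peak_polarities_exactly():
    x = np.random.default_rng(0).normal(size=N)
    ev_pos = peaks(x, FS)
    ev_neg = peaks(-x, FS)
    assert len(ev_pos) == len(ev_neg)
    for a, b in zip(ev_pos, ev_neg):
        assert a.polarity != b.polarity
        assert a.amplitude == pytest.approx(-b.amplitude)
        assert a.duration == b.duration
        assert a.time_to_peak == b.time_to_peak
    assert zero_crossings(x).size == zero_crossings(-x).size


def test_fewer_than_two_crossings_gives_no_peaks():
    assert peaks(np.linspace(-1, 1, 50), FS, remove_mean=False) == []


@given(hnp.arrays(np.float64, st.integers(30, 120),
                  elements=st.floats(-5, 5, allow_nan=False)))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_peak_segmentation_matches_brute_force_oracle(x):
    """Every inter-crossing segment yields exactly one event whose extremum
    matches a direct scan of that segment."""
    events = peaks(x, fs=1.0, remove_mean=True)
    xc = x - x.mean()
    zc = zero_crossings(xc, remove_mean=False)
    assert len(events) == max(0, len(zc) - 1)
    for e, (a, b) in zip(events, zip(zc[:-1], zc[1:])):
        seg = xc[a:b]
        expected = seg.max() if e.polarity == "positive" else seg.min()
        assert e.amplitude == expected
        assert 0 <= e.time_to_peak <= e.duration


def test_empty_event_statistics_follow_zero_convention():
    stats = peak_statistics([], zc_count=3)
    assert stats.shape == (33,)
    assert stats[0] == 3.0
    np.testing.assert_array_equal(stats[1:], 0.0)


def test_two_positive_peaks_duration_statistics_by_hand():
    ev = [
        PeakEvent("positive", 1.0, 0, 4, 0.4, 0.2),
        PeakEvent("positive", 2.0, 4, 10, 0.6, 0.1),
    ]
    stats = peak_statistics(ev, zc_count=3)
    # positive-duration block: mean, population std, max, min, range
    mean, std, mx, mn, rng = stats[3:8]
    assert mean == pytest.approx(0.5)
    assert std == pytest.approx(0.1)  # population estimator
    assert (mx, mn) == (0.6, 0.4)
    assert rng == pytest.approx(0.2)


def test_total_peak_count_pools_positive_and_negative():
    x = np.random.default_rng(1).normal(size=N)
    ev = peaks(x, FS)
    stats = peak_statistics(ev, zc_count=0)
    assert stats[1] + stats[2] == len(ev)


def test_constant_acceleration_integrates_to_ramp_and_parabola():
    a, dur = 2.0, 5.0
    x = np.full(int(dur * FS) + 1, a)
    v = integrate(x, FS, order=1, remove_mean=False)
    assert v[-1] == pytest.approx(a * dur, rel=1e-9)  # v = a t
    d = integrate(x, FS, order=2, remove_mean=False)
    assert d[-1] == pytest.approx(a * dur**2 / 2, rel=1e-3)  # trapezoid error


def test_sine_integral_rms_matches_closed_form():
    f = 1.0
    x = np.sin(2 * np.pi * f * T)
    v = integrate(x, FS, order=1)
    # ∫sin = -cos/(2πf) + C; with mean removal RMS -> 1/(2πf) · RMS(cos)
    analytic = 1.0 / (2 * np.pi * f) / np.sqrt(2)
    rms = np.sqrt(np.mean((v - v.mean()) ** 2))
    assert rms == pytest.approx(analytic, rel=0.02)


def test_feature_vector_length_and_block_structure(one_window):
    vec = extract_featset_b(one_window)
    assert vec.shape == (221,)
    assert len(FEATSET_B_NAMES) == 221
    assert len(set(FEATSET_B_NAMES)) == 221
    assert len(features_b.PER_CHANNEL_NAMES) == 33
    assert len(features_b.INTEGRATION_NAMES) == 23


def test_mirror_symmetry_swaps_polarity_blocks(one_window):
    """Negating all channels swaps positive/negative peak features and
    preserves the zero-crossing count, per channel."""
    w_neg = make_window(-one_window.channels, fs=one_window.fs)
    f_pos = extract_featset_b(one_window)
    f_neg = extract_featset_b(w_neg)
    names = list(FEATSET_B_NAMES)
    for ch in features_b.CHANNELS:
        i_zc = names.index(f"B__{ch}__n_zero_crossings")
        assert f_pos[i_zc] == f_neg[i_zc]
        i_p = names.index(f"B__{ch}__n_pos_peaks")
        i_n = names.index(f"B__{ch}__n_neg_peaks")
        assert f_pos[i_p] == f_neg[i_n]
        assert f_pos[i_n] == f_neg[i_p]
        for stat in ("mean", "std", "max", "min", "range"):
            ip = names.index(f"B__{ch}__duration_pos_{stat}")
            iq = names.index(f"B__{ch}__duration_neg_{stat}")
            assert f_pos[ip] == pytest.approx(f_neg[iq])


def test_durations_and_counts_are_well_bounded(one_window):
    vec = extract_featset_b(one_window)
    names = list(FEATSET_B_NAMES)
    window_len = one_window.n_samples / one_window.fs
    for i, name in enumerate(names):
        if "duration" in name or "time_to_peak" in name:
            assert 0 <= vec[i] <= window_len
        if name.endswith(("n_zero_crossings", "n_pos_peaks", "n_neg_peaks",
                          "n_total_peaks")):
            assert vec[i] >= 0 and vec[i] == int(vec[i])
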