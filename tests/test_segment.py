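"""Filtering, event detection, stance segmentation and time normalization."""

import numpy as np
import pytest

import gaitprog as gp
from gaitprog.segment import (GaitEvents, estimate_stride_s, lowpass_filter,
                              normalize_stance, pair_events, segment_stances)
from gaitprog.simulate import SubjectParams


# ---------------------------------------------------------------------------
# low-pass filter


def test_filter_preserves_constant():
    x = np.full(500, 3.7)
    np.testing.assert_allclose(lowpass_filter(x, fs=100.0), x, atol=1e-9)


def test_filter_is_zero_phase_on_inband_sinusoid():
    fs, f = 100.0, 2.0
    t = np.arange(2000) / fs
    x = np.sin(2 * np.pi * f * t)
    y = lowpass_filter(x, fs)
    # lag-0 maximum of the cross-correlation <=> no phase shift
    lags = np.arange(-10, 11)
    xc = [np.dot(y[10:-10], x[10 + l:len(x) - 10 + l]) for l in lags]
    assert lags[int(np.argmax(xc))] == 0


def test_filter_attenuation_matches_analytic_butterworth():
    # bidirectional 4th-order pass: |H(f)|^2 = 1/(1 + (f/fc)^8)
    fs, f = 1000.0, 30.0
    t = np.arange(20000) / fs
    y = lowpass_filter(np.sin(2 * np.pi * f * t), fs, cutoff_hz=20.0, order=4)
    measured = np.max(np.abs(y[5000:15000]))
    expected = 1.0 / (1.0 + (30.0 / 20.0) ** 8)
    assert measured == pytest.approx(expected, rel=0.02)


def test_filter_rejects_short_series():
    with pytest.raises(ValueError, match="too short"):
        lowpass_filter(np.zeros(10), fs=100.0)


def test_filter_idempotent_on_bandlimited_signal():
    fs = 100.0
    t = np.arange(3000) / fs
    x = np.sin(2 * np.pi * 3 * t) + 0.5 * np.sin(2 * np.pi * 7 * t)
    once = lowpass_filter(x, fs)
    twice = lowpass_filter(once, fs)
    rms = np.sqrt(np.mean((twice - once) ** 2)) / np.sqrt(np.mean(once ** 2))
    assert rms < 0.01


# ---------------------------------------------------------------------------
# event detection


def test_detection_recovers_planted_events_within_one_sample():
    spec = gp.CohortSpec(n_good=1, n_poor=0, cycles_per_subject=8, seed=0,
                         effects=gp.default_effects())
    params = SubjectParams("x", "Good", 1.1, 0.65)
    trial, truth = gp.generate_trial(spec, params, np.random.default_rng(3))
    ev = gp.detect_gait_events(gp.filter_trial(trial))
    assert len(ev.ic_indices) == len(truth["ic_indices"])
    assert np.max(np.abs(ev.ic_indices - truth["ic_indices"])) <= 1
    assert len(ev.to_indices) == len(truth["to_indices"])
    assert np.max(np.abs(ev.to_indices - truth["to_indices"])) <= 1


def test_flat_signal_gives_no_events():
    assert gp.detect_initial_contacts(np.zeros(1000), fs=100.0).size == 0


def _spike(x, i, height):
    x[i - 1] += 0.5 * height
    x[i] += height
    x[i + 1] += 0.5 * height


def test_close_peaks_keep_the_higher_one():
    fs = 100.0
    x = np.full(600, 0.05)  # small floor so the adaptive threshold is finite
    _spike(x, 200, 1.0)
    _spike(x, 230, 2.0)  # 0.3 s apart, below the 0.5 s separation
    idx = gp.detect_initial_contacts(x, fs, min_separation_s=0.5)
    assert list(idx) == [230]


def test_anterior_sign_flag_inverts_extremum():
    # a mounting with flipped polarity + flipped flag must reproduce the events
    spec = gp.CohortSpec(n_good=1, n_poor=0, cycles_per_subject=8, seed=0)
    trial, _ = gp.generate_trial(spec, SubjectParams("x", "Good", 1.1, 0.65),
                                 np.random.default_rng(7))
    x = gp.lowpass_filter(trial.channel("tibial_GYR_X"), trial.fs)
    up = gp.detect_toe_offs(x, trial.fs)
    down = gp.detect_toe_offs(-x, trial.fs, anterior_is_positive=False)
    assert up.size > 0
    np.testing.assert_array_equal(up, down)


def test_stride_estimate_from_autocorrelation():
    fs = 100.0
    t = np.arange(3000) / fs
    x = np.cos(2 * np.pi * t / 1.1)
    assert estimate_stride_s(x, fs) == pytest.approx(1.1, abs=0.02)


# ---------------------------------------------------------------------------
# stance segmentation


def _trial_of_length(n):
    return gp.ImuTrial(trial_id="t", fs=100.0,
                       lumbar=gp.SensorStream(np.zeros((n, 3)), np.zeros((n, 3))),
                       tibial=gp.SensorStream(np.ones((n, 3)), np.zeros((n, 3))))


def _events(n_cycles, start=50, stride=100, stance=60):
    ic = start + stride * np.arange(n_cycles)
    return GaitEvents(ic_indices=ic, to_indices=ic + stance)


@pytest.mark.parametrize("paired,retained", [(9, 5), (5, 1), (4, 0), (2, 0)])
def test_edge_exclusion_arithmetic(paired, retained):
    trial = _trial_of_length(50 + 100 * paired + 100)
    out = segment_stances(_events(paired), trial)
    assert len(out) == retained
    if retained:
        assert [sw.cycle_index for sw in out] == list(range(retained))


def test_stance_includes_both_event_samples():
    trial = _trial_of_length(1200)
    out = segment_stances(_events(9, stance=60), trial)
    assert all(sw.raw.shape[0] == 61 for sw in out)
    assert all(sw.duration_s == pytest.approx(0.60) for sw in out)


def test_to_before_first_ic_is_dropped():
    ev = GaitEvents(ic_indices=np.array([100, 200, 300, 400, 500, 600, 700]),
                    to_indices=np.array([40, 160, 260, 360, 460, 560, 660, 760]))
    pairs = pair_events(ev)
    assert pairs[0] == (100, 160)
    assert len(pairs) == 7


def test_double_ic_invalidates_earlier_one():
    ev = GaitEvents(ic_indices=np.array([100, 120, 200]),
                    to_indices=np.array([160, 260]))
    assert pair_events(ev) == [(120, 160), (200, 260)]


# ---------------------------------------------------------------------------
# 101-point normalization


def test_normalize_passes_through_101_knots():
    x = np.random.default_rng(0).random(101)
    out = normalize_stance(x, fs=100.0)
    np.testing.assert_allclose(out, x, atol=1e-9)


def test_normalize_reproduces_linear_ramp():
    x = np.linspace(2.0, 5.0, 37)
    out = normalize_stance(x, fs=100.0)
    np.testing.assert_allclose(out, np.linspace(2.0, 5.0, 101), atol=1e-9)


def test_normalize_against_dense_evaluation():
    # a 5 Hz sinusoid sampled at 30+ points re-normalized vs the dense truth
    fs, n = 100.0, 40
    t = np.arange(n) / fs
    x = np.sin(2 * np.pi * 5 * t)
    out = normalize_stance(x, fs)
    dense = np.sin(2 * np.pi * 5 * np.linspace(0, t[-1], 101))
    assert np.max(np.abs(out - dense)) < 1e-3


def test_normalize_rejects_tiny_input():
    with pytest.raises(ValueError):
        normalize_stance(np.array([1.0, 2.0, 3.0]), fs=100.0)
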