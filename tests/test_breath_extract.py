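"""Turning angles, transition detection, arc length and the waveform."""

import numpy as np
import pytest

from csibreath.breath_extract import (
    TURN_THRESHOLD_RAD,
    arc_length,
    build_waveform,
    detect_transitions,
    extract_breathing,
    refine_transitions,
    turning_angles,
)
from csibreath.trajectory_fit import fit_segment


class _Path:
    """Minimal trajectory stand-in: timestamps plus complex values."""

    def __init__(self, t, v):
        self.timestamps = np.asarray(t, float)
        self.values = np.asarray(v, complex)


# ----------------------------------------------------------------------
# turning angles
# ----------------------------------------------------------------------

@pytest.mark.parametrize(
    "points,expected",
    [
        ([0, 1, 1 + 1j], np.pi / 2),  # perpendicular
        ([0, 1, 0], np.pi),  # reversal
        ([0, 1, 2], 0.0),  # straight
    ],
)
def test_turning_angle_unit_cases(points, expected):
    ang = turning_angles(np.asarray(points, complex))
    assert ang[0] == pytest.approx(expected, abs=1e-12)


def test_turning_angle_zero_displacement_is_no_turn():
    ang = turning_angles(np.asarray([0, 0, 1], complex))
    assert ang[0] == 0.0


def test_turning_angle_lag():
    # same reversal seen through lag-2 displacement vectors
    v = np.asarray([0, 1, 2, 1, 0], complex)
    ang = turning_angles(v, lag=2)
    assert ang[0] == pytest.approx(np.pi)
    with pytest.raises(ValueError):
        turning_angles(v, lag=0)
    with pytest.raises(ValueError):
        turning_angles(v[:3], lag=2)


# ----------------------------------------------------------------------
# transition detection
# ----------------------------------------------------------------------

def test_back_and_forth_gives_single_transition():
    t = np.arange(21) / 10.0
    v = np.concatenate([np.linspace(0, 1, 11), np.linspace(1, 0, 11)[1:]])
    ang = turning_angles(v.astype(complex))
    trans = detect_transitions(ang, t[1:-1], min_separation=0.5)
    assert trans.size == 1
    assert trans[0] == pytest.approx(1.0)  # at the reversal


def test_circle_has_no_transitions():
    n = 32
    t = np.arange(n) / 10.0
    v = np.exp(2j * np.pi * np.arange(n) / n)
    ang = turning_angles(v)
    assert np.all(ang < TURN_THRESHOLD_RAD)  # per-step turn = 2 pi / 32
    assert detect_transitions(ang, t[1:-1]).size == 0


def test_detect_threshold_validation():
    with pytest.raises(ValueError):
        detect_transitions(np.zeros(5), np.arange(5.0), threshold=0.0)
    with pytest.raises(ValueError):
        detect_transitions(np.zeros(5), np.arange(4.0))


# ----------------------------------------------------------------------
# arc length
# ----------------------------------------------------------------------

def test_arc_length_straight_segment():
    p = _Path([0.0, 1.0], [0.0, 3.0 + 4.0j])
    assert arc_length(p, 0.0, 1.0) == pytest.approx(5.0, abs=1e-12)


def test_arc_length_unit_semicircle():
    t = np.linspace(0, 1, 400)
    p = _Path(t, np.exp(1j * np.pi * t))
    assert arc_length(p, 0.0, 1.0) == pytest.approx(np.pi, abs=1e-3)


def test_arc_length_degenerate_and_bounds():
    t = np.linspace(0, 1, 10)
    p = _Path(t, t.astype(complex))
    assert arc_length(p, 0.5, 0.5) == 0.0
    with pytest.raises(ValueError):
        arc_length(p, -0.5, 0.5)
    with pytest.raises(ValueError):
        arc_length(p, 0.8, 0.2)


def test_arc_length_uses_basis_form_for_fitted_trajectory():
    t = np.linspace(0, 10, 400)
    q = np.exp(2j * np.pi * t / 5.0)
    fit = fit_segment(t, q, p=30, s=0.35)
    # full circle traversed twice in 10 s -> length ~ 4 pi
    assert arc_length(fit, 0.5, 9.5) == pytest.approx(
        arc_length(_Path(t, q), 0.5, 9.5), rel=2e-2
    )


# ----------------------------------------------------------------------
# waveform
# ----------------------------------------------------------------------

def test_waveform_without_transitions_is_monotone_arc():
    t = np.linspace(0, 1, 50)
    p = _Path(t, (t * (3 + 4j)).astype(complex))
    res = build_waveform(p, np.empty(0))
    assert res.waveform[0] == 0.0
    assert np.all(np.diff(res.waveform) >= 0)
    assert res.waveform[-1] == pytest.approx(5.0, abs=1e-9)


def test_waveform_triangle_on_reversal_path():
    t = np.arange(21) / 10.0
    v = np.concatenate([np.linspace(0, 2, 11), np.linspace(2, 0, 11)[1:]])
    p = _Path(t, v.astype(complex))
    res = build_waveform(p, np.array([1.0]))
    assert res.waveform[10] == pytest.approx(2.0)  # peak at |AB|
    assert res.waveform[-1] == pytest.approx(0.0, abs=1e-9)
    # |S_i - S_{i-1}| equals the local chord length
    assert np.allclose(np.abs(np.diff(res.waveform)), np.abs(np.diff(v)))
    # sign flips exactly at the transition
    assert np.all(res.flags[1:11] == 1) and np.all(res.flags[11:] == -1)


def test_waveform_isometry_invariance():
    t = np.linspace(0, 6, 200)
    v = np.exp(2j * np.pi * t / 3.0) * (1 + 0.3 * np.sin(t))
    rot = np.exp(1j * 0.77)
    shift = 2.5 - 1.0j
    a = extract_breathing([fit_segment(t, v, p=20, s=0.3)], angle_lag_s=0.3)
    b = extract_breathing(
        [fit_segment(t, v * rot + shift, p=20, s=0.3)], angle_lag_s=0.3
    )
    assert np.allclose(a.waveform, b.waveform, atol=1e-8)
    assert np.allclose(a.transition_times, b.transition_times)


def test_time_reversal_maps_waveform_to_reversed_negation():
    t = np.arange(31) / 10.0
    fwd = np.concatenate(
        [np.linspace(0, 2, 11), np.linspace(2, 1, 11)[1:], np.linspace(1, 1.8, 11)[1:]]
    ).astype(complex)
    rev = fwd[::-1]
    T_fwd = np.array([1.0, 2.0])
    T_rev = np.array([3.0 - 2.0, 3.0 - 1.0])
    s_f = build_waveform(_Path(t, fwd), T_fwd).waveform
    s_r = build_waveform(_Path(t, rev), T_rev).waveform
    flipped = s_f[::-1]
    match = [
        np.allclose(s_r - s_r.mean(), sign * (flipped - flipped.mean()), atol=1e-9)
        for sign in (1, -1)
    ]
    assert any(match)


def test_rate_from_median_intervals():
    # 15 transitions spaced exactly 2 s apart -> 4 s cycles -> 15 bpm
    T = np.arange(15) * 2.0
    t = np.linspace(0, 30, 601)
    v = np.exp(1j * 0.1 * t)
    res = build_waveform(_Path(t, v), T)
    assert res.rate_bpm == pytest.approx(15.0)
    assert np.allclose(res.cycle_intervals, 4.0)


def test_refine_transitions_preserves_count_and_order(quiet_run):
    _, _, truth, out = quiet_run
    seg = out.segments[0]
    refined = refine_transitions(seg, out.result.transition_times)
    assert refined.size == out.result.transition_times.size
    assert np.all(np.diff(refined) > 0)
    assert refine_transitions(seg, np.empty(0)).size == 0


def test_trough_dwell_exceeds_peak_dwell(quiet_run):
    """The longer exhale-to-inhale pause shows up as denser point
    aggregation (longer low-speed dwell) at troughs than at peaks."""
    cfg, _, truth, out = quiet_run
    seg = out.segments[0]
    t, v = seg.timestamps, seg.values
    speed = np.abs(np.diff(v))
    ts = t[1:]
    lo = speed < 0.25 * np.median(speed)
    dwell = {0: 0.0, 1: 0.0}
    for k, tau in enumerate(truth.transition_times):
        sel = np.abs(ts - tau) < 0.6
        dwell[k % 2] += float(lo[sel].sum())
    # generator convention: even-index transitions are peaks
    assert dwell[1] > dwell[0]
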