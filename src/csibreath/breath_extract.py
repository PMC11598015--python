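"""Breath-transition detection and signed arc-length waveform.

During quiet breathing the smoothed CSI-ratio trajectory sweeps along a
curve on the I/Q plane while the chest moves, then reverses at each
breath transition.  A reversal shows up as a large angle (near pi)
between successive displacement vectors of the fitted trajectory; turns
above 2*pi/3 are taken as transitions.  The breathing waveform S is the
cumulative arc length travelled on the I/Q plane, with its sign flipped
at each transition — chest displacement mapped back from trajectory
speed, up to an arbitrary global sign (inhale vs exhale is not
observable from arc length alone).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

from .trajectory_fit import FittedTrajectory

TURN_THRESHOLD_RAD = 2.0 * np.pi / 3.0


@dataclass
class BreathResult:
    """Transitions, waveform and breathing rate for one record."""

    transition_times: np.ndarray  # s, increasing
    timestamps: np.ndarray  # waveform grid
    waveform: np.ndarray  # S, signed cumulative arc length
    flags: np.ndarray  # +1/-1 direction trace per grid point
    cycle_intervals: np.ndarray  # s, successive same-direction gaps
    rate_bpm: float
    segment_slices: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.transition_times = np.asarray(self.transition_times, dtype=float)
        if self.transition_times.size > 1 and np.any(
            np.diff(self.transition_times) <= 0
        ):
            raise ValueError("transition times must be increasing")


def _displacements(traj) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(getattr(traj, "values", traj), dtype=complex)
    times = np.asarray(getattr(traj, "timestamps", np.arange(values.size)), float)
    return times, values


def turning_angles(traj, lag: int = 1) -> np.ndarray:
    """Absolute turn between successive displacement vectors, in [0, pi].

    For interior grid point i the angle is the four-quadrant
    ``|atan2(cross, dot)|`` of the displacement vectors Q[i]-Q[i-lag]
    and Q[i+lag]-Q[i]; zero-length displacements carry angle 0 (no
    turn).  ``lag`` sets the time granularity of the displacement
    vectors: during the pause at a breath transition the trajectory is
    nearly stationary, so adjacent-sample displacements there are
    noise; vectors spanning roughly the pause duration make the
    reversal angle sharp.  The result aligns with grid points
    ``lag .. n-lag-1``.  Accepts a FittedTrajectory or a plain complex
    array.
    """
    _, values = _displacements(traj)
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if values.size < 2 * lag + 1:
        raise ValueError("need at least 2*lag + 1 fitted points")
    a = values[lag:-lag] - values[:-2 * lag]
    b = values[2 * lag:] - values[lag:-lag]
    # conj(a) * b encodes dot + j*cross of the two displacement vectors
    prod = np.conj(a) * b
    angles = np.abs(np.angle(prod))
    angles[(np.abs(a) == 0) | (np.abs(b) == 0)] = 0.0
    return angles


def detect_transitions(
    angles: np.ndarray,
    times: np.ndarray,
    threshold: float = TURN_THRESHOLD_RAD,
    min_separation: float = 0.8,
) -> np.ndarray:
    """Times of turns exceeding `threshold`, thinned by `min_separation`.

    `times` are the interior grid times the angles refer to.  A
    transition is a local maximum of the angle series above the
    threshold; maxima closer together than `min_separation` collapse to
    the largest (scipy peak picking) — a reversal smeared over the lag
    span produces a broad supra-threshold cluster with a single peak,
    and a genuine half-breath is never shorter than `min_separation`.
    """
    if not 0 < threshold <= np.pi:
        raise ValueError("threshold must lie in (0, pi]")
    angles = np.asarray(angles, dtype=float)
    times = np.asarray(times, dtype=float)
    if angles.size != times.size:
        raise ValueError("angles and times must align")
    if angles.size < 3:
        return np.empty(0)
    dt = float(np.median(np.diff(times)))
    distance = max(1, int(round(min_separation / dt)))
    peaks, _ = find_peaks(angles, height=threshold, distance=distance)
    # a lone supra-threshold plateau at the array edge is still a turn
    if peaks.size == 0 and angles.max() > threshold:
        peaks = np.array([int(np.argmax(angles))])
    return times[peaks]


def arc_length(traj, t_a: float, t_b: float, refine: int = 4) -> float:
    """Arc length of the trajectory between two times on the I/Q plane.

    Computed as the chord-length sum on a grid refined by `refine`
    between the trajectory's own samples; a FittedTrajectory is refined
    through its basis form, anything else through a cubic spline of its
    sampled values (linear below 4 points).
    """
    times, values = _displacements(traj)
    if t_a > t_b:
        raise ValueError("t_a must not exceed t_b")
    if t_a < times[0] - 1e-9 or t_b > times[-1] + 1e-9:
        raise ValueError("times outside the fitted segment")
    if t_a == t_b:
        return 0.0
    inside = (times > t_a) & (times < t_b)
    knots = np.concatenate([[t_a], times[inside], [t_b]])
    n_fine = (knots.size - 1) * max(1, refine) + 1
    fine = np.linspace(t_a, t_b, n_fine)
    if isinstance(traj, FittedTrajectory):
        vals = traj.evaluate(fine)
    elif times.size >= 4:
        spline = CubicSpline(times, values)
        vals = spline(fine)
    else:
        vals = np.interp(fine, times, values.real) + 1j * np.interp(
            fine, times, values.imag
        )
    return float(np.sum(np.abs(np.diff(vals))))


def refine_transitions(
    traj,
    transitions: np.ndarray,
    search_s: float = 0.5,
) -> np.ndarray:
    """Sharpen transition times by local mirror symmetry of the motion.

    Around a breath transition the one-dimensional breathing coordinate
    (the trajectory projected on its local principal direction) is
    approximately time-symmetric: a deceleration ramp, a pause, and the
    mirrored acceleration ramp.  For each detected transition the time
    within ``search_s`` that maximises the mirror correlation
    sum_u x(c+u)·x(c-u) is taken; this uses the high-velocity ramps on
    both sides to localise the pause centre, which the turning-angle
    peak alone places only to within the pause duration.
    """
    times, values = _displacements(traj)
    transitions = np.asarray(transitions, dtype=float)
    if transitions.size == 0 or times.size < 9:
        return transitions
    dt = float(np.median(np.diff(times)))
    gaps = np.diff(transitions)
    default_gap = float(np.median(gaps)) if gaps.size else 2.0
    refined = []
    for k, tau in enumerate(transitions):
        g_prev = gaps[k - 1] if k > 0 else default_gap
        g_next = gaps[k] if k < gaps.size else default_gap
        half = 0.7 * min(g_prev, g_next)
        sel = (times >= tau - half - search_s) & (times <= tau + half + search_s)
        if sel.sum() < 9:
            refined.append(tau)
            continue
        tw = times[sel]
        z = values[sel] - values[sel].mean()
        xy = np.column_stack([z.real, z.imag])
        _, vecs = np.linalg.eigh(xy.T @ xy)
        x = xy @ vecs[:, -1]
        x -= x.mean()
        i0 = int(np.argmin(np.abs(tw - tau)))
        reach = int(round(half / dt))
        shift = int(round(search_s / dt))
        best, best_score = None, -np.inf
        for di in range(-shift, shift + 1):
            c = i0 + di
            m = min(reach, c, x.size - 1 - c)
            if m < 4:
                continue
            score = float(np.dot(x[c + 1:c + m + 1], x[c - m:c][::-1])) / m
            if score > best_score:
                best_score, best = score, c
        refined.append(float(tw[best]) if best is not None else tau)
    refined = np.asarray(refined)
    # keep the original time wherever refinement would break the ordering
    bad = np.flatnonzero(np.diff(refined) <= 0)
    if bad.size:
        refined[bad] = transitions[bad]
        refined[bad + 1] = transitions[bad + 1]
        if np.any(np.diff(refined) <= 0):
            return transitions
    return refined


def _rate_from_transitions(transitions: np.ndarray) -> tuple[float, np.ndarray]:
    """Breathing rate from transition times; edge partials excluded.

    Successive same-direction transition gaps are full-cycle intervals;
    with three or more of them the rate is 60 / median(interval), which
    shrugs off a single missed or spurious turn.  With fewer, fall back
    to counting half-cycles over the transition span.
    """
    transitions = np.asarray(transitions, dtype=float)
    intervals = transitions[2:] - transitions[:-2] if transitions.size >= 3 \
        else np.empty(0)
    if intervals.size >= 3:
        return 60.0 / float(np.median(intervals)), intervals
    if transitions.size >= 2:
        span = transitions[-1] - transitions[0]
        half_cycles = transitions.size - 1
        return 60.0 * (half_cycles / 2.0) / span, intervals
    return float("nan"), intervals


def build_waveform(
    traj: FittedTrajectory,
    transitions: np.ndarray,
) -> BreathResult:
    """Cumulative signed arc length with sign flips at each transition.

    Per Algorithm convention the direction flag starts at +1 and negates
    at every transition; S[0] = 0 and each step adds flag times the
    local arc length.
    """
    t, q = _displacements(traj)
    if t.size == 0:
        raise ValueError("empty trajectory")
    dl = np.abs(np.diff(q))
    flip_idx = set()
    for tt in np.asarray(transitions, dtype=float):
        flip_idx.add(int(np.argmin(np.abs(t - tt))))
    flags = np.ones(t.size)
    flag = 1.0
    for i in range(1, t.size):
        # the step ending at the transition still moves in the old
        # direction; the flip takes effect on the step leaving it
        if i - 1 in flip_idx:
            flag = -flag
        flags[i] = flag
    s = np.concatenate([[0.0], np.cumsum(flags[1:] * dl)])
    rate, intervals = _rate_from_transitions(transitions)
    return BreathResult(
        transition_times=np.asarray(transitions, dtype=float),
        timestamps=t,
        waveform=s,
        flags=flags,
        cycle_intervals=intervals,
        rate_bpm=rate,
        segment_slices=[(0, t.size)],
    )


def extract_breathing(
    segments: Sequence[FittedTrajectory],
    *,
    threshold: float = TURN_THRESHOLD_RAD,
    min_separation: float = 0.8,
    angle_lag_s: float = 0.8,
    refine: bool = True,
) -> BreathResult:
    """Transitions, waveform and rate over all clean segments.

    Each contiguous clean segment is processed independently (gaps left
    by motion filtering are not bridged); segment rates are combined
    with duration weights, and the concatenated waveform restarts at
    zero on each segment.  ``angle_lag_s`` is the time span of the
    displacement vectors the turning angles are computed over (about
    the breath-transition pause duration).
    """
    if not segments:
        raise ValueError("no fitted segments to extract from")
    parts: list[BreathResult] = []
    for traj in segments:
        t = traj.timestamps
        dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
        lag = max(1, int(round(angle_lag_s / dt)))
        if t.size < 2 * lag + 1:
            parts.append(build_waveform(traj, np.empty(0)))
            continue
        ang = turning_angles(traj, lag=lag)
        trans = detect_transitions(
            ang, t[lag:-lag], threshold, min_separation
        )
        if refine:
            trans = refine_transitions(traj, trans)
        parts.append(build_waveform(traj, trans))

    timestamps = np.concatenate([p.timestamps for p in parts])
    waveform = np.concatenate([p.waveform for p in parts])
    flags = np.concatenate([p.flags for p in parts])
    transition_times = np.concatenate([p.transition_times for p in parts])
    intervals = np.concatenate([p.cycle_intervals for p in parts])

    weights, rates = [], []
    for p_res, traj in zip(parts, segments):
        if np.isfinite(p_res.rate_bpm):
            weights.append(traj.timestamps[-1] - traj.timestamps[0])
            rates.append(p_res.rate_bpm)
    rate = float(np.average(rates, weights=weights)) if rates else float("nan")

    slices = []
    off = 0
    for p_res in parts:
        slices.append((off, off + p_res.timestamps.size))
        off += p_res.timestamps.size
    return BreathResult(
        transition_times=transition_times,
        timestamps=timestamps,
        waveform=waveform,
        flags=flags,
        cycle_intervals=intervals,
        rate_bpm=rate,
        segment_slices=slices,
    )
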