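"""Dispersion-based rejection of gross body-motion interference.

Quiet breathing moves the CSI-ratio point slowly along its I/Q
trajectory, so within a short window the samples stay tightly grouped.
Gross motion (arm waving, body swaying) scatters them.  The dispersion
statistic D of a window is the (W-1)-normalised mean squared deviation
of the ratio samples from their window mean, averaged over subcarriers
and summed over admitted link pairs; windows with D above a fixed
threshold (default 0.001) are labelled interference and their samples
excluded from trajectory fitting and breathing extraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import Link, RatioSeries


@dataclass
class DispersionSeries:
    window_start_times: np.ndarray  # s
    window_start_idx: np.ndarray  # sample index of each window start
    D: np.ndarray  # dispersion per window, >= 0 (inf if window unusable)
    window_w: int  # samples
    stride: int  # samples
    n_samples: int
    links_used: list[tuple[Link, Link]]

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if np.any(self.D < 0):
            raise ValueError("dispersion must be non-negative")


@dataclass
class MotionMask:
    flags: np.ndarray  # True = interference, one per ratio-grid sample
    threshold: float

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)


def window_dispersion(
    ratios: Sequence[RatioSeries] | RatioSeries,
    window_w: int,
    stride: int | None = None,
) -> DispersionSeries:
    """Windowed dispersion D of CSI-ratio samples.

    For each admitted pair of distinct links, the squared deviations of
    that pair's ratio from the window mean are summed with 1/(W-1)
    normalisation and averaged over the pair's subcarriers; D is the sum
    over pairs.  Windows are placed every `stride` samples (default
    W//2, 50% overlap) with a final window flushed to the record end so
    every sample is covered.
    """
    if isinstance(ratios, RatioSeries):
        ratios = [ratios]
    if not ratios:
        raise ValueError("no ratio series given")
    if window_w < 2:
        raise ValueError("window must span at least 2 samples (W >= 2)")
    if stride is None:
        stride = max(1, window_w // 2)

    t0 = ratios[0].timestamps
    n = t0.size
    for r in ratios[1:]:
        if r.n != n or not np.allclose(r.timestamps, t0, atol=1e-9, rtol=0.0):
            raise ValueError("all ratio series must share one grid")
    if window_w > n:
        raise ValueError("window longer than the record")

    # group subcarriers by (numerator, denominator) link pair
    pairs: dict[tuple[Link, Link], list[RatioSeries]] = {}
    for r in ratios:
        if r.num_link == r.den_link:
            raise ValueError("dispersion admits only pairs of distinct links")
        pairs.setdefault((r.num_link, r.den_link), []).append(r)

    starts = list(range(0, n - window_w + 1, stride))
    if starts[-1] != n - window_w:
        starts.append(n - window_w)
    starts_arr = np.asarray(starts, dtype=int)

    D = np.zeros(starts_arr.size)
    for wi, s in enumerate(starts_arr):
        total = 0.0
        for series_list in pairs.values():
            acc = 0.0
            for r in series_list:
                seg = r.values[s:s + window_w][r.valid[s:s + window_w]]
                if seg.size < 2:
                    acc = np.inf
                    break
                dev = seg - seg.mean()
                acc += float(np.sum(np.abs(dev) ** 2)) / (window_w - 1)
            total += acc / len(series_list)
        D[wi] = total

    return DispersionSeries(
        window_start_times=t0[starts_arr],
        window_start_idx=starts_arr,
        D=D,
        window_w=window_w,
        stride=stride,
        n_samples=n,
        links_used=list(pairs.keys()),
    )


def label_interference(
    dispersion: DispersionSeries,
    threshold: float = 0.001,
    close_gap: int = 0,
) -> MotionMask:
    """Flag every sample covered by a window whose D exceeds `threshold`.

    A sample inside several overlapping windows is flagged if any of
    them exceeds the threshold: motion contamination in a window spreads
    through any fit that uses it.  ``close_gap`` (samples) additionally
    merges flagged regions separated by shorter clean gaps — gross
    motion is not obliged to keep the dispersion continuously high, and
    a sub-second lull between two flagged stretches is still motion.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    flags = np.zeros(dispersion.n_samples, dtype=bool)
    for s, d in zip(dispersion.window_start_idx, dispersion.D):
        if d > threshold:
            flags[s:s + dispersion.window_w] = True
    if close_gap > 0 and flags.any():
        idx = np.flatnonzero(flags)
        gaps = np.flatnonzero(np.diff(idx) > 1)
        runs = np.split(idx, gaps + 1)
        for a, b in zip(runs[:-1], runs[1:]):
            if b[0] - a[-1] - 1 <= close_gap:
                flags[a[-1]:b[0] + 1] = True
    return MotionMask(flags=flags, threshold=threshold)
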