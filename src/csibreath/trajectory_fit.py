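"""Gaussian-basis least-squares smoothing of the I/Q ratio trajectory.

The clean ratio samples are projected onto p Gaussian bumps whose
centres are spread evenly across the segment's time window; real and
imaginary channels are fitted independently with a shared design matrix
(the squared-error objective makes the complex fit exactly separable).
The smoothed trajectory is what the turning-angle breath extractor
operates on: raw samples are too noisy for reliable inflection-point
detection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .containers import RatioSeries
from .motion_filter import MotionMask


@dataclass
class FittedTrajectory:
    """Smoothed complex trajectory of one contiguous clean segment."""

    timestamps: np.ndarray
    values: np.ndarray  # fitted Q-hat on the segment grid
    beta: np.ndarray  # (p, 2) coefficients, real/imag channels
    p: int
    s: float  # smoothness (bump width), seconds
    window: tuple[float, float]  # segment time range the centres span
    offset: complex = 0.0 + 0.0j  # mean removed before the fit
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("basis order p must be >= 1")
        if self.s <= 0:
            raise ValueError("smoothness s must be positive")
        if self.timestamps.size != self.values.size:
            raise ValueError("fitted length must equal grid length")

    def evaluate(self, times: np.ndarray) -> np.ndarray:
        """Evaluate the fitted curve at arbitrary times (basis form)."""
        phi = _design(np.asarray(times, dtype=float), self.p, self.s, self.window)
        re_im = phi @ self.beta
        return re_im[:, 0] + 1j * re_im[:, 1] + self.offset


def gaussian_basis(
    t: np.ndarray | float,
    d: int,
    p: int,
    s: float,
    window: tuple[float, float],
) -> np.ndarray | float:
    """Unit-height Gaussian bump centred at the d-th of p spread centres.

    Centres sit at fractional positions d/(p+1), d = 1..p, of the
    segment's time window, so the fit is invariant to global time
    translation of the segment.
    """
    if not 1 <= d <= p:
        raise ValueError(f"basis index d={d} outside 1..{p}")
    if s <= 0:
        raise ValueError("smoothness s must be positive")
    t0, t1 = window
    center = t0 + (t1 - t0) * d / (p + 1)
    return np.exp(-((np.asarray(t, dtype=float) - center) ** 2) / (2.0 * s**2))


def _design(t: np.ndarray, p: int, s: float, window: tuple[float, float]) -> np.ndarray:
    t0, t1 = window
    centers = t0 + (t1 - t0) * np.arange(1, p + 1) / (p + 1)
    return np.exp(-((t[:, None] - centers[None, :]) ** 2) / (2.0 * s**2))


def auto_hyperparameters(
    duration_s: float, expected_period_s: float = 4.0
) -> tuple[int, float]:
    """Default basis order and width.

    Bump spacing is a quarter of the expected breath period, capped at
    0.5 s so that faster-than-expected breathing (up to ~30 breaths/min)
    still gets at least four bumps per cycle; widths overlap
    neighbouring bumps.
    """
    spacing = min(0.5, expected_period_s / 4.0)
    p = max(4, math.ceil(duration_s / spacing))
    s = duration_s / (p + 1)
    return p, s


def fit_segment(
    t: np.ndarray,
    q: np.ndarray,
    *,
    p: int | None = None,
    s: float | None = None,
    expected_period_s: float = 4.0,
    ridge: float = 1e-8,
    center: bool = True,
) -> FittedTrajectory:
    """Least-squares Gaussian-basis fit of one contiguous segment.

    A tiny ridge term stabilises the normal equations (neighbouring
    bumps are nearly collinear at large p).  With ``center`` the segment
    mean is removed before the fit and restored afterwards, so the
    basis only has to represent the motion around the static offset.
    """
    t = np.asarray(t, dtype=float)
    q = np.asarray(q, dtype=complex)
    window = (float(t[0]), float(t[-1]))
    duration = window[1] - window[0]
    if p is None or s is None:
        p_auto, s_auto = auto_hyperparameters(duration, expected_period_s)
        p = p_auto if p is None else p
        s = s_auto if s is None else s
    if t.size < p:
        raise ValueError(
            f"underdetermined segment: {t.size} samples for p={p} bases"
        )

    offset = complex(q.mean()) if center else 0.0 + 0.0j
    y = np.column_stack([(q - offset).real, (q - offset).imag])
    phi = _design(t, p, s, window)
    gram = phi.T @ phi + ridge * np.eye(p)
    beta = np.linalg.solve(gram, phi.T @ y)
    fitted = phi @ beta
    resid = y - fitted
    values = fitted[:, 0] + 1j * fitted[:, 1] + offset
    return FittedTrajectory(
        timestamps=t,
        values=values,
        beta=beta,
        p=p,
        s=float(s),
        window=window,
        offset=offset,
        residual_rms=float(np.sqrt(np.mean(np.abs(resid[:, 0] + 1j * resid[:, 1]) ** 2))),
    )


def clean_segments(
    ratio: RatioSeries, mask: MotionMask | None = None, min_samples: int = 8
) -> list[np.ndarray]:
    """Index arrays of contiguous clean (unmasked, valid) runs."""
    keep = ratio.valid.copy()
    if mask is not None:
        if mask.flags.size != ratio.n:
            raise ValueError("mask length does not match the ratio grid")
        keep &= ~mask.flags
    segments: list[np.ndarray] = []
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return segments
    breaks = np.flatnonzero(np.diff(idx) > 1)
    for run in np.split(idx, breaks + 1):
        if run.size >= min_samples:
            segments.append(run)
    return segments


def fit_trajectory(
    ratio: RatioSeries,
    mask: MotionMask | None = None,
    *,
    p: int | None = None,
    s: float | None = None,
    expected_period_s: float = 4.0,
    ridge: float = 1e-8,
    center: bool = True,
) -> list[FittedTrajectory]:
    """Fit each contiguous clean segment of the ratio independently.

    Segments with fewer clean samples than basis functions are skipped
    with a warning (filtered motion can leave short fragments that
    cannot support a fit).
    """
    out: list[FittedTrajectory] = []
    for run in clean_segments(ratio, mask):
        t = ratio.timestamps[run]
        q = ratio.values[run]
        try:
            out.append(
                fit_segment(
                    t, q, p=p, s=s, expected_period_s=expected_period_s,
                    ridge=ridge, center=center,
                )
            )
        except ValueError as exc:
            warnings.warn(f"skipping segment [{t[0]:.2f}, {t[-1]:.2f}] s: {exc}")
    return out
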