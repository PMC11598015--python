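"""Preprocessing: GP interpolation, static removal, two-link CSI ratio.

Raw CSI arrives non-uniformly in time (packet delivery jitter), carries a
constant static component (line of sight plus fixed reflectors) and a
random common phase from carrier frequency offset and packet detection
delay.  This module turns it into a uniformly sampled complex ratio
series between two rx chains, in which the common phase cancels exactly:

    H1d / H2d = (a1 / a2) * exp(-j * 2*pi * f * (tau1 - tau2))

leaving only the geometry difference between the two reflection paths —
the quantity that tracks breathing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .containers import CsiSeries, RatioSeries


@dataclass
class GpModel:
    """Fitted RBF-kernel hyperparameters for the interpolator."""

    length_scale: float  # seconds
    signal_variance: float
    noise_variance: float
    log_marginal_likelihood: float

    def __post_init__(self) -> None:
        if self.length_scale <= 0:
            raise ValueError("length_scale must be positive")


# ----------------------------------------------------------------------
# Gaussian-process interpolation onto a uniform grid
# ----------------------------------------------------------------------

def _fit_hyperparameters(
    t: np.ndarray,
    y: np.ndarray,
    length_scale_bounds: tuple[float, float],
    initial_length_scales: tuple[float, ...],
    max_fit_samples: int,
) -> tuple[GaussianProcessRegressor, GpModel]:
    """Maximise the marginal likelihood on a contiguous sample window.

    Hyperparameters are fitted on a contiguous window (capped at
    ``max_fit_samples`` points, taken from the middle of the record) so
    the cost stays cubic in a small constant rather than in the record
    length; the short-range structure that determines the length scale
    is fully represented in any such window.  Restarts from three fixed
    initial length scales; the best likelihood wins.
    """
    m = min(t.size, max_fit_samples)
    i0 = (t.size - m) // 2
    tf, yf = t[i0:i0 + m], y[i0:i0 + m]

    lo, hi = length_scale_bounds
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for l0 in initial_length_scales:
            l0 = float(np.clip(l0, lo, hi))
            kernel = ConstantKernel(1.0, (1e-4, 1e4)) * RBF(
                l0, (lo, hi)
            ) + WhiteKernel(1e-3, (1e-10, 1e1))
            gpr = GaussianProcessRegressor(
                kernel=kernel, alpha=1e-10, normalize_y=True,
                n_restarts_optimizer=0, random_state=0,
            )
            gpr.fit(tf[:, None], yf)
            lml = gpr.log_marginal_likelihood_value_
            if best is None or lml > best[1]:
                best = (gpr, lml)
    gpr, lml = best
    k = gpr.kernel_
    model = GpModel(
        length_scale=float(k.k1.k2.length_scale),
        signal_variance=float(k.k1.k1.constant_value),
        noise_variance=float(k.k2.noise_level),
        log_marginal_likelihood=float(lml),
    )
    return gpr, model


def interpolate_gp(
    series: CsiSeries,
    grid_rate: float,
    *,
    grid: np.ndarray | None = None,
    length_scale_bounds: tuple[float, float] = (0.05, 5.0),
    initial_length_scales: tuple[float, ...] = (0.1, 0.5, 2.0),
    max_fit_samples: int = 192,
    block_s: float = 12.0,
    return_model: bool = False,
    fixed_model: GpModel | None = None,
):
    """Resample a non-uniform complex series onto a uniform grid.

    Real and imaginary parts are modelled as two outputs of one Gaussian
    process with a shared RBF length scale; the posterior mean at the
    grid times is the interpolated value.  Prediction is blockwise with
    a 4-length-scale pad so long records stay tractable.

    Parameters
    ----------
    series : CsiSeries with >= 4 samples, strictly increasing timestamps.
    grid_rate : target uniform sampling rate, samples/s.
    grid : optional explicit grid (overrides `grid_rate` spacing origin);
        must lie within the observed time range.
    fixed_model : reuse previously fitted hyperparameters instead of
        refitting — e.g. to share one length scale across the rx chains
        of a device, whose streams sample the same physical process on
        the same clock (independent fits can land on different length
        scales and smooth the two chains asymmetrically, which distorts
        their ratio).
    """
    t = series.timestamps
    if t.size < 4:
        raise ValueError("need at least 4 samples for GP interpolation")
    y = np.column_stack([series.values.real, series.values.imag])

    if grid is None:
        n_out = int(np.floor((t[-1] - t[0]) * grid_rate)) + 1
        grid = t[0] + np.arange(n_out) / grid_rate
    else:
        grid = np.asarray(grid, dtype=float)
        if grid[0] < t[0] - 1e-9 or grid[-1] > t[-1] + 1e-9:
            raise ValueError("grid extends beyond the observed time range")

    if fixed_model is None:
        gpr_fit, model = _fit_hyperparameters(
            t, y, length_scale_bounds, initial_length_scales, max_fit_samples
        )
        kernel = gpr_fit.kernel_
    else:
        model = fixed_model
        kernel = ConstantKernel(model.signal_variance) * RBF(
            model.length_scale
        ) + WhiteKernel(model.noise_variance)
    pad = max(4.0 * model.length_scale, 0.25)

    out = np.empty((grid.size, 2))
    start = 0
    while start < grid.size:
        stop = min(grid.size, start + max(1, int(round(block_s * grid_rate))))
        g = grid[start:stop]
        sel = (t >= g[0] - pad) & (t <= g[-1] + pad)
        if sel.sum() < 2:  # pragma: no cover - grid within range guarantees data
            sel = slice(None)
        gpr = GaussianProcessRegressor(
            kernel=kernel, alpha=1e-10, normalize_y=True, optimizer=None
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gpr.fit(t[sel, None] if isinstance(sel, np.ndarray) else t[:, None],
                    y[sel] if isinstance(sel, np.ndarray) else y)
        out[start:stop] = gpr.predict(g[:, None])
        start = stop

    interp = CsiSeries(
        timestamps=grid,
        values=out[:, 0] + 1j * out[:, 1],
        link=series.link,
        subcarrier=series.subcarrier,
        freq_hz=series.freq_hz,
    )
    if return_model:
        return interp, model
    return interp


# ----------------------------------------------------------------------
# static component
# ----------------------------------------------------------------------

def _moving_mean(x: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    n = x.size
    c = np.concatenate([[0.0 + 0.0j], np.cumsum(x)])
    half = w // 2
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + (w - half), 0, n)
    return (c[hi] - c[lo]) / (hi - lo)


def estimate_static(
    series: CsiSeries,
    window_s: float = 10.0,
    mode: str = "prefix",
):
    """Estimate the static (time-constant) component of one CSI stream.

    In a static window the dynamic term averages to (near) zero, so the
    windowed mean of the complex samples estimates Hs.

    mode="prefix": single complex mean over the first `window_s` seconds
    (a calibration prefix assumed free of large motion).
    mode="moving": per-sample centered moving average of width `window_s`
    (edges use shrunken windows); returns an array of the input length.
    """
    if series.n == 0:
        raise ValueError("empty series")
    if mode == "prefix":
        sel = series.timestamps <= series.timestamps[0] + window_s
        if sel.sum() < 2:
            raise ValueError("calibration window covers fewer than 2 samples")
        return complex(series.values[sel].mean())
    if mode == "moving":
        dt = np.median(np.diff(series.timestamps)) if series.n > 1 else 1.0
        w = max(2, int(round(window_s / dt)))
        return _moving_mean(series.values, w)
    raise ValueError(f"unknown mode {mode!r}")


def remove_static(series: CsiSeries, static) -> CsiSeries:
    """Subtract a static estimate (scalar or per-sample) elementwise."""
    return series.with_values(series.values - np.asarray(static))


# ----------------------------------------------------------------------
# two-link ratio
# ----------------------------------------------------------------------

def csi_ratio(
    numerator: CsiSeries,
    denominator: CsiSeries,
    *,
    amp_floor: float | None = None,
    amp_floor_factor: float = 1e-3,
    allow_same_link: bool = False,
) -> RatioSeries:
    """Complex ratio Q(t) = H_num(t) / H_den(t) of two aligned links.

    Samples whose denominator magnitude falls below the amplitude floor
    (default: ``amp_floor_factor`` times the median |H_den|) are marked
    invalid and set to NaN; downstream stages skip them.
    """
    if numerator.n != denominator.n or not np.allclose(
        numerator.timestamps, denominator.timestamps, atol=1e-9, rtol=0.0
    ):
        raise ValueError("numerator and denominator grids are not aligned")
    if numerator.link == denominator.link and not allow_same_link:
        raise ValueError("ratio requires two different links")

    den = denominator.values
    if amp_floor is None:
        amp_floor = amp_floor_factor * float(np.median(np.abs(den)))
    valid = np.abs(den) >= amp_floor
    q = np.full(den.shape, np.nan + 1j * np.nan)
    q[valid] = numerator.values[valid] / den[valid]
    return RatioSeries(
        timestamps=numerator.timestamps,
        values=q,
        num_link=numerator.link,
        den_link=denominator.link,
        subcarrier=numerator.subcarrier,
        freq_hz=numerator.freq_hz,
        valid=valid,
    )
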