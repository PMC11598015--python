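"""End-to-end extraction pipeline.

Stage order: GP interpolation of each rx stream onto a shared uniform
grid -> (optional) static removal -> two-link ratio -> dispersion-based
motion mask -> Gaussian-basis trajectory fit per clean segment ->
turning-point transition detection and signed arc-length waveform ->
(metrics, when a reference is available).  Every stage logs its sample
counts and parameters; the run is deterministic for a given config.
"""

from __future__ import annotations

import logging
import platform
import time
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .breath_extract import BreathResult, extract_breathing
from .config import PipelineConfig
from .containers import CsiSeries, RatioSeries
from .metrics import MetricsReport, evaluate_against_truth
from .motion_filter import MotionMask, label_interference, window_dispersion
from .preprocess import csi_ratio, estimate_static, interpolate_gp, remove_static
from .synthetic_csi import SimTruth
from .trajectory_fit import FittedTrajectory, fit_trajectory

log = logging.getLogger("csibreath.pipeline")


class PipelineError(RuntimeError):
    """Numerical failure inside a pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineOutput:
    result: BreathResult
    ratio: RatioSeries
    mask: MotionMask
    segments: list[FittedTrajectory]
    metrics: MetricsReport | None
    provenance: dict = field(default_factory=dict)


def _select_streams(
    series_map: dict[tuple[int, int, int], CsiSeries],
    subcarrier: int | None,
) -> tuple[list[int], int]:
    """Pick the tx=1 rx chains and the working subcarrier."""
    keys = [k for k in series_map if k[0] == 1]
    if not keys:
        raise PipelineError("select", "no streams for tx antenna 1")
    rxs = sorted({k[1] for k in keys})
    if len(rxs) < 2:
        raise PipelineError("select", "ratio requires two rx chains")
    subs = sorted({k[2] for k in keys})
    if subcarrier is None:
        subcarrier = subs[len(subs) // 2]
    elif subcarrier not in subs:
        raise PipelineError("select", f"subcarrier {subcarrier} not present")
    return rxs[:2], subcarrier


def run_pipeline(
    config: PipelineConfig,
    series_map: dict[tuple[int, int, int], CsiSeries],
    truth: SimTruth | None = None,
) -> PipelineOutput:
    """Run the full extraction on a CSI stream collection."""
    t_start = time.perf_counter()
    (rx_num, rx_den), sub = _select_streams(series_map, config.subcarrier)
    subs_all = sorted(
        {k[2] for k in series_map if k[0] == 1 and k[1] in (rx_num, rx_den)}
    )
    log.info(
        "streams: tx=1 rx=(%d,%d), subcarriers=%s (working: %d)",
        rx_num, rx_den, subs_all, sub,
    )

    # shared uniform grid over the common observed range
    num0 = series_map[(1, rx_num, sub)]
    den0 = series_map[(1, rx_den, sub)]
    g0 = max(num0.timestamps[0], den0.timestamps[0])
    g1 = min(num0.timestamps[-1], den0.timestamps[-1])
    n_grid = int(np.floor((g1 - g0) * config.grid_rate)) + 1
    grid = g0 + np.arange(n_grid) / config.grid_rate

    gp_kw = dict(
        grid=grid,
        length_scale_bounds=(config.gp_length_scale_min, config.gp_length_scale_max),
        max_fit_samples=config.gp_max_fit_samples,
    )

    ratios: list[RatioSeries] = []
    working = None
    gp_model = None  # fitted once, shared across both chains and subcarriers
    try:
        for m in subs_all:
            num_u, gp_model = interpolate_gp(
                series_map[(1, rx_num, m)], config.grid_rate,
                return_model=True, fixed_model=gp_model, **gp_kw
            )
            den_u = interpolate_gp(
                series_map[(1, rx_den, m)], config.grid_rate,
                fixed_model=gp_model, **gp_kw
            )
            if config.ratio_on_dynamic:
                num_u = remove_static(
                    num_u,
                    estimate_static(num_u, config.static_window_s, config.static_mode),
                )
                den_u = remove_static(
                    den_u,
                    estimate_static(den_u, config.static_window_s, config.static_mode),
                )
            r = csi_ratio(num_u, den_u, amp_floor_factor=config.amp_floor_factor)
            ratios.append(r)
            if m == sub:
                working = r
        log.info(
            "interpolate+ratio: %d grid samples at %.3g Hz, %d subcarrier(s)",
            n_grid, config.grid_rate, len(ratios),
        )
    except (np.linalg.LinAlgError, FloatingPointError) as exc:
        raise PipelineError("preprocess", str(exc)) from exc

    w = max(2, int(round(config.dispersion_window_s * config.grid_rate)))
    stride = max(1, int(round(config.dispersion_stride_s * config.grid_rate)))
    disp = window_dispersion(ratios, w, stride)
    mask = label_interference(
        disp, config.dispersion_threshold,
        close_gap=int(round(config.mask_close_gap_s * config.grid_rate)),
    )
    log.info(
        "dispersion: W=%d stride=%d threshold=%g -> %d/%d samples flagged",
        w, stride, config.dispersion_threshold, int(mask.flags.sum()), n_grid,
    )

    segments = fit_trajectory(
        working,
        mask,
        p=config.basis_p,
        s=config.basis_s,
        expected_period_s=config.expected_breath_period_s,
        ridge=config.ridge,
    )
    if not segments:
        raise PipelineError("fit", "no clean segment long enough to fit")
    log.info(
        "fit: %d segment(s), residual RMS %s",
        len(segments), [round(s.residual_rms, 5) for s in segments],
    )

    result = extract_breathing(
        segments,
        threshold=config.transition_threshold_rad,
        min_separation=config.min_separation_s,
        angle_lag_s=config.angle_lag_s,
        refine=config.refine_transitions,
    )
    log.info(
        "extract: %d transitions, rate %.2f bpm",
        result.transition_times.size, result.rate_bpm,
    )

    report = evaluate_against_truth(result, truth) if truth is not None else None

    provenance = {
        "config_hash": config.content_hash(),
        "config": config.to_dict(),
        "csibreath_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "n_grid_samples": n_grid,
        "n_flagged": int(mask.flags.sum()),
        "n_segments": len(segments),
        "elapsed_s": round(time.perf_counter() - t_start, 3),
    }
    return PipelineOutput(
        result=result,
        ratio=working,
        mask=mask,
        segments=segments,
        metrics=report,
        provenance=provenance,
    )
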