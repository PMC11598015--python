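"""Scoring of extracted breathing against a reference.

Three standard metrics:

* ACC — per-breath interval accuracy, mean of
  (t_ref - |t_ref - t_det|) / t_ref over paired breaths (1 = perfect,
  0 when the detected interval is off by a full reference interval).
* MAE — mean absolute error between min-max-normalised waveforms on a
  common time base.
* AER — absolute difference of the two breathing rates, breaths/min.

The reference may be a wearable device's record or, for synthetic
studies, the simulator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .breath_extract import BreathResult
from .synthetic_csi import SimTruth


@dataclass
class MetricsReport:
    acc: float
    mae: float
    aer: float
    acc_per_minute: list[float] = field(default_factory=list)
    rate_reference_bpm: float = float("nan")
    rate_detected_bpm: float = float("nan")

    def __post_init__(self) -> None:
        if np.isfinite(self.mae) and self.mae < 0:
            raise ValueError("MAE must be non-negative")
        if np.isfinite(self.aer) and self.aer < 0:
            raise ValueError("AER must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


# ----------------------------------------------------------------------
# ACC
# ----------------------------------------------------------------------

def _pair_terms(
    reference_intervals: np.ndarray,
    detected_intervals: np.ndarray,
    reference_times: np.ndarray | None,
    detected_times: np.ndarray | None,
    gate_factor: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-reference-breath accuracy terms and their anchor times.

    With anchor times, each detected breath is greedily matched to the
    nearest unmatched reference onset within a gate of
    `gate_factor` * median reference interval; unmatched reference
    breaths score 0.  Without times, breaths pair by index.
    """
    ref = np.asarray(reference_intervals, dtype=float)
    det = np.asarray(detected_intervals, dtype=float)
    if ref.size == 0 or det.size == 0:
        raise ValueError("interval lists must be non-empty")
    terms = np.zeros(ref.size)
    if reference_times is None or detected_times is None:
        k = min(ref.size, det.size)
        terms[:k] = (ref[:k] - np.abs(ref[:k] - det[:k])) / ref[:k]
        anchors = np.cumsum(np.concatenate([[0.0], ref[:-1]]))
        return terms, anchors

    rt = np.asarray(reference_times, dtype=float)
    dt = np.asarray(detected_times, dtype=float)
    gate = gate_factor * float(np.median(ref))
    taken = np.zeros(ref.size, dtype=bool)
    order = np.argsort(dt)
    for j in order:
        dist = np.abs(rt - dt[j])
        dist[taken] = np.inf
        i = int(np.argmin(dist))
        if dist[i] <= gate:
            taken[i] = True
            terms[i] = (ref[i] - abs(ref[i] - det[j])) / ref[i]
    return terms, rt


def acc(
    reference_intervals,
    detected_intervals,
    *,
    reference_times=None,
    detected_times=None,
    gate_factor: float = 0.5,
) -> float:
    """Breathing-interval accuracy, global mean over reference breaths."""
    terms, _ = _pair_terms(
        np.asarray(reference_intervals, float),
        np.asarray(detected_intervals, float),
        reference_times, detected_times, gate_factor,
    )
    return float(terms.mean())


def acc_per_minute(
    reference_intervals,
    detected_intervals,
    *,
    reference_times=None,
    detected_times=None,
    gate_factor: float = 0.5,
) -> list[float]:
    """ACC terms averaged within successive one-minute bins."""
    terms, anchors = _pair_terms(
        np.asarray(reference_intervals, float),
        np.asarray(detected_intervals, float),
        reference_times, detected_times, gate_factor,
    )
    minute = np.floor((anchors - anchors[0]) / 60.0).astype(int)
    return [float(terms[minute == m].mean()) for m in np.unique(minute)]


# ----------------------------------------------------------------------
# MAE
# ----------------------------------------------------------------------

def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo <= 0:
        raise ValueError("constant signal: min-max normalisation undefined")
    return (x - lo) / (hi - lo)


def mae(extracted_waveform, reference_waveform) -> float:
    """Mean absolute difference of min-max-normalised signals.

    Both inputs must already share a common length/time base; use
    :func:`waveform_mae` to resample and score pipeline output.
    """
    phi = _minmax(np.asarray(extracted_waveform, dtype=float))
    g = _minmax(np.asarray(reference_waveform, dtype=float))
    if phi.size != g.size:
        raise ValueError("signals must share a common length")
    return float(np.mean(np.abs(phi - g)))


def waveform_mae(
    extracted_t,
    extracted,
    reference_t,
    reference,
) -> float:
    """MAE after resampling the reference onto the extracted grid.

    The arc-length waveform's global sign is an arbitrary convention,
    so the score is taken for both orientations and the smaller wins.
    """
    et = np.asarray(extracted_t, dtype=float)
    ev = np.asarray(extracted, dtype=float)
    keep = np.isfinite(ev)
    et, ev = et[keep], ev[keep]
    ref = np.interp(et, np.asarray(reference_t, float), np.asarray(reference, float))
    return min(mae(ev, ref), mae(-ev, ref))


# ----------------------------------------------------------------------
# AER
# ----------------------------------------------------------------------

def aer(rate_reference: float, rate_detected: float) -> float:
    """Absolute breathing-rate error in breaths/min."""
    if rate_reference < 0 or rate_detected < 0:
        raise ValueError("rates must be non-negative")
    return abs(float(rate_reference) - float(rate_detected))


# ----------------------------------------------------------------------
# scoring against simulator truth
# ----------------------------------------------------------------------

def intervals_from_transitions(transitions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full-breath intervals (same-direction transition gaps) + anchors."""
    t = np.asarray(transitions, dtype=float)
    if t.size < 3:
        return np.empty(0), np.empty(0)
    return t[2:] - t[:-2], t[:-2]


def evaluate_against_truth(result: BreathResult, truth: SimTruth) -> MetricsReport:
    """Score a pipeline result against simulator ground truth."""
    ref_int, ref_anchor = intervals_from_transitions(truth.transition_times)
    det_int, det_anchor = intervals_from_transitions(result.transition_times)
    if ref_int.size and det_int.size:
        acc_val = acc(
            ref_int, det_int,
            reference_times=ref_anchor, detected_times=det_anchor,
        )
        per_min = acc_per_minute(
            ref_int, det_int,
            reference_times=ref_anchor, detected_times=det_anchor,
        )
    else:
        acc_val, per_min = 0.0, []
    mae_val = waveform_mae(
        result.timestamps, result.waveform,
        truth.timestamps, truth.displacement,
    )
    aer_val = aer(truth.true_rate_bpm, result.rate_bpm) if np.isfinite(
        result.rate_bpm
    ) else float("inf")
    return MetricsReport(
        acc=acc_val,
        mae=mae_val,
        aer=aer_val,
        acc_per_minute=per_min,
        rate_reference_bpm=float(truth.true_rate_bpm),
        rate_detected_bpm=float(result.rate_bpm),
    )
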