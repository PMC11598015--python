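"""Synthetic multi-antenna CSI with known breathing ground truth.

The simulator realises the standard two-component channel model for a
person breathing near a WiFi link: a constant static component ``Hs``
(line of sight plus fixed reflectors) and a dynamic component
``A * exp(-j * 2*pi * d(t) / lambda)`` reflected off the chest, whose
path length ``d(t)`` follows quasi-sinusoidal chest displacement with a
short pause at each breath transition (the exhale-to-inhale pause being
slightly longer than the inhale-to-exhale one).  All receive chains of
one device share a common time-varying random phase psi(t) emulating
carrier frequency offset and packet detection delay; the two-link ratio
cancels it exactly, which is the property the pipeline relies on.

Sampling timestamps are a nominal uniform grid perturbed by Gaussian
jitter (packets are not delivered on a perfect clock).  Optional motion
bursts inflate the dynamic amplitude and superimpose an independent
random-walk displacement, emulating gross body motion such as arm
waving.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .containers import CsiSeries

SPEED_OF_LIGHT = 299_792_458.0
SUBCARRIER_SPACING_HZ = 312_500.0  # 802.11n 40 MHz subcarrier spacing


@dataclass(frozen=True)
class SimConfig:
    """Scene and acquisition parameters for one simulated record.

    Per-receive-antenna sequences (``static_component_per_link`` etc.)
    are indexed by rx chain; scalars broadcast.  ``geometry_gain_per_link``
    is the fraction of chest displacement projected onto each rx path —
    antennas roughly half a metre apart see the moving chest under
    different geometry, which is what makes the two-link ratio move with
    breathing at all.
    """

    duration: float = 120.0
    nominal_rate_hz: float = 20.0
    timestamp_jitter_sd: float = 0.005
    breathing_rate_bpm: float = 15.0
    chest_amplitude: float = 0.008  # m, peak-to-peak chest displacement
    pause_exhale_to_inhale: float = 0.5  # s, trough pause
    pause_inhale_to_exhale: float = 0.3  # s, peak pause
    wavelength: float = 0.0579  # m (5.18 GHz mid-channel)
    static_component_per_link: tuple[complex, ...] = (1.0 + 0.3j, 0.8 - 0.2j)
    dynamic_gain_per_link: tuple[float, ...] = (0.30, 0.24)
    geometry_gain_per_link: tuple[float, ...] = (1.0, 0.45)
    base_path_per_link: tuple[float, ...] = (3.000, 3.117)  # m, resting d
    noise_sd: float = 0.005  # per-component complex Gaussian SD
    phase_noise_step_sd: float = 0.05  # rad/sample random-walk step of psi
    motion_bursts: tuple[tuple[float, float, float], ...] = ()
    burst_walk_step: float = 0.002  # m/sample random-walk step inside bursts
    n_tx: int = 1
    n_rx: int = 2
    n_subcarriers: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.nominal_rate_hz <= 0:
            raise ValueError("nominal_rate_hz must be positive")
        if self.breathing_rate_bpm <= 0:
            raise ValueError("breathing_rate_bpm must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_rx < 2:
            raise ValueError("need n_rx >= 2: the ratio requires two rx chains")
        if self.pause_exhale_to_inhale <= self.pause_inhale_to_exhale:
            raise ValueError(
                "pause_exhale_to_inhale must exceed pause_inhale_to_exhale"
            )
        period = 60.0 / self.breathing_rate_bpm
        if self.pause_exhale_to_inhale + self.pause_inhale_to_exhale >= period:
            raise ValueError("pauses do not fit inside one breathing period")

    # -- convenience -------------------------------------------------

    @property
    def period_s(self) -> float:
        return 60.0 / self.breathing_rate_bpm

    @property
    def ramp_s(self) -> float:
        """Duration of each inhale/exhale ramp."""
        return 0.5 * (
            self.period_s
            - self.pause_exhale_to_inhale
            - self.pause_inhale_to_exhale
        )

    def per_rx(self, values, rx: int):
        """Broadcast a scalar or per-rx sequence to rx chain `rx` (1-based)."""
        if np.isscalar(values):
            return values
        seq = list(values)
        return seq[(rx - 1) % len(seq)]


@dataclass
class SimTruth:
    """Ground truth carried alongside a simulated record."""

    timestamps: np.ndarray
    displacement: np.ndarray  # m, chest displacement d(t) at `timestamps`
    transition_times: np.ndarray  # s, direction-reversal times (2 / cycle)
    true_rate_bpm: float
    motion_mask: np.ndarray  # True where inside a motion burst
    n_full_cycles: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.transition_times = np.asarray(self.transition_times, dtype=float)
        self.motion_mask = np.asarray(self.motion_mask, dtype=bool)
        if np.any(np.diff(self.transition_times) <= 0):
            raise ValueError("transition_times must be strictly increasing")


# ----------------------------------------------------------------------
# displacement model
# ----------------------------------------------------------------------

def displacement_at(config: SimConfig, t: np.ndarray) -> np.ndarray:
    """Chest displacement d(t) in metres at arbitrary times.

    One breathing cycle, phase-referenced to the start of an inhale ramp:
    half-cosine rise (ramp_s) -> peak pause (inhale->exhale) ->
    half-cosine fall (ramp_s) -> trough pause (exhale->inhale).
    Half-cosine ramps are C1 at the pause boundaries, so the simulated
    I/Q trajectory has no artificial corners that could alias as breath
    transitions.
    """
    t = np.asarray(t, dtype=float)
    amp = config.chest_amplitude
    if amp == 0.0:
        return np.zeros_like(t)
    period = config.period_s
    ramp = config.ramp_s
    p_peak = config.pause_inhale_to_exhale
    u = np.mod(t, period)
    d = np.empty_like(u)

    rising = u < ramp
    at_peak = (u >= ramp) & (u < ramp + p_peak)
    falling = (u >= ramp + p_peak) & (u < 2 * ramp + p_peak)
    at_trough = u >= 2 * ramp + p_peak

    d[rising] = 0.5 * amp * (1.0 - np.cos(np.pi * u[rising] / ramp))
    d[at_peak] = amp
    d[falling] = 0.5 * amp * (
        1.0 + np.cos(np.pi * (u[falling] - ramp - p_peak) / ramp)
    )
    d[at_trough] = 0.0
    return d


def transition_times(config: SimConfig) -> np.ndarray:
    """Direction-reversal times (pause midpoints), two per cycle."""
    period = config.period_s
    ramp = config.ramp_s
    peak_rev = ramp + 0.5 * config.pause_inhale_to_exhale
    trough_rev = 2 * ramp + config.pause_inhale_to_exhale + \
        0.5 * config.pause_exhale_to_inhale
    times = []
    k = 0
    while True:
        base = k * period
        done = True
        for rev in (peak_rev, trough_rev):
            tt = base + rev
            if tt <= config.duration:
                times.append(tt)
                done = False
        if done:
            break
        k += 1
    return np.asarray(times, dtype=float)


def simulate_displacement(config: SimConfig) -> tuple[np.ndarray, np.ndarray, SimTruth]:
    """Sample d(t) on the nominal uniform grid and build ground truth."""
    n = int(round(config.duration * config.nominal_rate_hz))
    t = np.arange(n) / config.nominal_rate_hz
    d = displacement_at(config, t)
    truth = SimTruth(
        timestamps=t,
        displacement=d,
        transition_times=transition_times(config),
        true_rate_bpm=config.breathing_rate_bpm,
        motion_mask=np.zeros(n, dtype=bool),
        n_full_cycles=int(math.floor(config.duration / config.period_s)),
        seed=config.seed,
    )
    return t, d, truth


# ----------------------------------------------------------------------
# CSI synthesis
# ----------------------------------------------------------------------

def _jittered_timestamps(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n = int(round(config.duration * config.nominal_rate_hz))
    t = np.arange(n) / config.nominal_rate_hz
    if config.timestamp_jitter_sd > 0:
        t = np.sort(t + rng.normal(0.0, config.timestamp_jitter_sd, n))
        # enforce strict monotonicity after sorting (ties are measure-zero
        # but protect against them anyway)
        eps = 1e-9
        for _ in range(3):
            bad = np.diff(t) <= 0
            if not bad.any():
                break
            t[1:][bad] = t[:-1][bad] + eps
    return t


def _burst_state(
    config: SimConfig, t: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample (motion mask, amplitude multiplier, extra displacement)."""
    n = t.size
    mask = np.zeros(n, dtype=bool)
    mult = np.ones(n)
    extra = np.zeros(n)
    for start, end, amp_mult in config.motion_bursts:
        inside = (t >= start) & (t < end)
        mask |= inside
        mult[inside] = np.maximum(mult[inside], amp_mult)
        k = int(inside.sum())
        if k:
            extra[inside] += np.cumsum(
                rng.normal(0.0, config.burst_walk_step, k)
            )
    return mask, mult, extra


def subcarrier_frequencies(config: SimConfig) -> np.ndarray:
    f0 = SPEED_OF_LIGHT / config.wavelength
    m = np.arange(1, config.n_subcarriers + 1)
    return f0 + (m - 0.5 * (config.n_subcarriers + 1)) * SUBCARRIER_SPACING_HZ


def simulate_csi(
    config: SimConfig,
    *,
    disable_phase_noise: bool = False,
) -> tuple[dict[tuple[int, int, int], CsiSeries], SimTruth]:
    """Generate one record of CSI streams plus its ground truth.

    Returns a mapping keyed by (tx, rx, subcarrier) — all 1-based.
    ``disable_phase_noise`` reruns the identical scene with psi(t) = 0
    (same seed, same draw order) for cancellation oracles.
    """
    rng = np.random.default_rng(config.seed)
    t = _jittered_timestamps(config, rng)
    n = t.size
    psi_steps = rng.normal(0.0, config.phase_noise_step_sd, n)
    psi = np.cumsum(psi_steps)
    if disable_phase_noise or config.phase_noise_step_sd == 0.0:
        psi = np.zeros(n)
    mask, mult, extra_disp = _burst_state(config, t, rng)

    d = displacement_at(config, t) + extra_disp
    freqs = subcarrier_frequencies(config)
    phase_factor = np.exp(-1j * psi)

    out: dict[tuple[int, int, int], CsiSeries] = {}
    for tx in range(1, config.n_tx + 1):
        for rx in range(1, config.n_rx + 1):
            hs = complex(config.per_rx(config.static_component_per_link, rx))
            gain = float(config.per_rx(config.dynamic_gain_per_link, rx))
            geom = float(config.per_rx(config.geometry_gain_per_link, rx))
            base = float(config.per_rx(config.base_path_per_link, rx))
            path = base + geom * d
            for m, f in enumerate(freqs, start=1):
                lam = SPEED_OF_LIGHT / f
                dyn = gain * mult * np.exp(-2j * np.pi * path / lam)
                noise = rng.normal(0.0, config.noise_sd, n) + 1j * rng.normal(
                    0.0, config.noise_sd, n
                ) if config.noise_sd > 0 else 0.0
                h = phase_factor * (hs + dyn + noise)
                out[(tx, rx, m)] = CsiSeries(
                    timestamps=t, values=h, link=(tx, rx),
                    subcarrier=m, freq_hz=float(f),
                )

    truth = SimTruth(
        timestamps=t,
        displacement=displacement_at(config, t),
        transition_times=transition_times(config),
        true_rate_bpm=config.breathing_rate_bpm,
        motion_mask=mask,
        n_full_cycles=int(math.floor(config.duration / config.period_s)),
        seed=config.seed,
    )
    return out, truth


# ----------------------------------------------------------------------
# study-condition presets
# ----------------------------------------------------------------------

#: Chest orientation presets (degrees from vertical).  Orientation changes
#: the chest's projected area in the reflection: 60 deg presents the
#: largest effective reflector, 30 deg is partially shadowed.  Encoded as
#: dynamic-gain scaling plus a rotated static vector (different standing
#: multipath per pose).
ORIENTATION_PRESETS: Mapping[int, dict] = {
    90: {"gain_scale": 1.0, "static_phase_deg": 0.0},
    60: {"gain_scale": 1.25, "static_phase_deg": 40.0},
    30: {"gain_scale": 0.70, "static_phase_deg": -55.0},
}

#: Monitoring-distance presets: dynamic gain falls with distance while
#: effective noise rises.
DISTANCE_PRESETS: Mapping[int, dict] = {
    1: {"gain_scale": 1.0, "noise_scale": 1.0},
    2: {"gain_scale": 0.5, "noise_scale": 1.5},
    3: {"gain_scale": 1.0 / 3.0, "noise_scale": 2.0},
}


def orientation_config(base: SimConfig, orientation_deg: int) -> SimConfig:
    p = ORIENTATION_PRESETS[orientation_deg]
    rot = np.exp(1j * np.deg2rad(p["static_phase_deg"]))
    return replace(
        base,
        dynamic_gain_per_link=tuple(
            g * p["gain_scale"] for g in base.dynamic_gain_per_link
        ),
        static_component_per_link=tuple(
            complex(s * rot) for s in base.static_component_per_link
        ),
    )


def distance_config(base: SimConfig, distance_level: int) -> SimConfig:
    p = DISTANCE_PRESETS[distance_level]
    return replace(
        base,
        dynamic_gain_per_link=tuple(
            g * p["gain_scale"] for g in base.dynamic_gain_per_link
        ),
        noise_sd=base.noise_sd * p["noise_scale"],
    )
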