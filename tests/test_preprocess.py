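"""GP interpolation, static estimation/removal and the two-link ratio."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from csibreath.containers import CsiSeries
from csibreath.preprocess import (
    GpModel,
    csi_ratio,
    estimate_static,
    interpolate_gp,
    remove_static,
)
from csibreath.synthetic_csi import SimConfig, simulate_csi


def _series(t, v, link=(1, 1)):
    return CsiSeries(timestamps=np.asarray(t, float), values=np.asarray(v, complex), link=link)


# ----------------------------------------------------------------------
# interpolate_gp
# ----------------------------------------------------------------------

def test_gp_constant_input_reproduced(rng):
    t = np.sort(rng.uniform(0, 10, 80))
    c = 1.5 - 0.75j
    out = interpolate_gp(_series(t, np.full(80, c)), grid_rate=10.0)
    assert np.max(np.abs(out.values - c)) < 1e-6
    dt = np.diff(out.timestamps)
    assert np.allclose(dt, dt[0], atol=1e-9)


def test_gp_recovers_jittered_sinusoid(rng):
    """Noise-free 4 s-period sinusoid sampled at 20 Hz with +-20 ms jitter."""
    n = 400
    t = np.sort(np.arange(n) / 20.0 + rng.uniform(-0.02, 0.02, n))
    t = np.maximum.accumulate(t + np.arange(n) * 1e-12)
    v = np.exp(2j * np.pi * t / 4.0)
    out = interpolate_gp(_series(t, v), grid_rate=20.0)
    expected = np.exp(2j * np.pi * out.timestamps / 4.0)
    assert np.max(np.abs(out.values - expected)) < 1e-2


def test_gp_posterior_mean_reproduces_observations_as_noise_vanishes(rng):
    t = np.sort(rng.uniform(0, 8, 60))
    v = np.sin(t) + 1j * np.cos(0.5 * t)
    model = GpModel(
        length_scale=0.5, signal_variance=1.0,
        noise_variance=1e-12, log_marginal_likelihood=0.0,
    )
    out = interpolate_gp(
        _series(t, v), grid_rate=10.0, grid=t, fixed_model=model
    )
    assert np.max(np.abs(out.values - v)) < 1e-4


def test_gp_too_few_samples_rejected():
    with pytest.raises(ValueError):
        interpolate_gp(_series([0.0, 1.0, 2.0], [1, 1, 1]), grid_rate=10.0)


# ----------------------------------------------------------------------
# static component
# ----------------------------------------------------------------------

def test_static_mean_of_two_samples():
    s = _series([0.0, 1.0], [1 + 0j, 3 + 0j])
    assert estimate_static(s, window_s=2.0) == pytest.approx(2 + 0j)


def test_static_recovers_configured_component():
    cfg = SimConfig(
        duration=20.0, chest_amplitude=0.0, noise_sd=0.0,
        phase_noise_step_sd=0.0, dynamic_gain_per_link=(0.0, 0.0),
    )
    series, _ = simulate_csi(cfg)
    est = estimate_static(series[(1, 1, 1)], window_s=10.0, mode="prefix")
    assert est == pytest.approx(cfg.static_component_per_link[0], abs=1e-12)


def test_static_moving_mode_preserves_length(rng):
    t = np.arange(50) / 10.0
    v = rng.normal(size=50) + 1j * rng.normal(size=50)
    out = estimate_static(_series(t, v), window_s=1.0, mode="moving")
    assert out.shape == (50,)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.complex_numbers(max_magnitude=10, allow_nan=False, allow_infinity=False)
)
def test_static_translation_equivariance(c):
    t = np.arange(20) / 5.0
    v = np.exp(1j * t)
    base = estimate_static(_series(t, v), window_s=10.0)
    shifted = estimate_static(_series(t, v + c), window_s=10.0)
    assert shifted == pytest.approx(base + c, abs=1e-9)


def test_remove_static_inverse_and_zero():
    t = np.arange(10) / 5.0
    v = np.exp(1j * t) + (2 - 1j)
    s = _series(t, v)
    dyn = remove_static(s, 2 - 1j)
    assert np.allclose(dyn.values + (2 - 1j), v)
    zero = remove_static(_series(t, np.full(10, 2 - 1j)), 2 - 1j)
    assert np.allclose(zero.values, 0.0)


def test_residual_magnitude_equals_dynamic_gain():
    cfg = SimConfig(
        duration=20.0, noise_sd=0.0, phase_noise_step_sd=0.0,
        timestamp_jitter_sd=0.0,
    )
    series, _ = simulate_csi(cfg)
    s = series[(1, 1, 1)]
    dyn = remove_static(s, cfg.static_component_per_link[0])
    assert np.allclose(np.abs(dyn.values), cfg.dynamic_gain_per_link[0], atol=1e-12)


# ----------------------------------------------------------------------
# csi_ratio
# ----------------------------------------------------------------------

def test_ratio_of_identical_streams_is_one():
    t = np.arange(10) / 5.0
    v = np.exp(1j * t) * (1 + 0.5j)
    q = csi_ratio(_series(t, v, (1, 1)), _series(t, v, (1, 1)), allow_same_link=True)
    assert np.allclose(q.values, 1.0 + 0.0j)


def test_ratio_complex_division_example():
    t = np.array([0.0, 0.1])
    num = _series(t, np.full(2, 2 * np.exp(1j * np.pi / 2)), (1, 1))
    den = _series(t, np.full(2, 1 * np.exp(1j * np.pi / 4)), (1, 2))
    q = csi_ratio(num, den)
    assert np.allclose(q.values, 2 * np.exp(1j * np.pi / 4))


def test_ratio_shared_phase_invariance(rng):
    t = np.arange(50) / 10.0
    h1 = np.exp(1j * t) + 0.5
    h2 = np.exp(0.7j * t) + 0.8
    psi = rng.uniform(-np.pi, np.pi, 50)
    q0 = csi_ratio(_series(t, h1, (1, 1)), _series(t, h2, (1, 2)))
    q1 = csi_ratio(
        _series(t, h1 * np.exp(1j * psi), (1, 1)),
        _series(t, h2 * np.exp(1j * psi), (1, 2)),
    )
    assert np.max(np.abs(q1.values - q0.values)) < 1e-9


def test_ratio_single_path_modulus_and_phase():
    """Pure single-path inputs close the ratio algebra: |Q| = a1/a2 and
    arg Q = -2 pi f (tau1 - tau2)."""
    f = 5.18e9
    tau1, tau2 = 1.001e-8, 1.0e-8
    a1, a2 = 0.8, 0.5
    t = np.arange(8) / 20.0
    h1 = a1 * np.exp(-2j * np.pi * f * tau1) * np.ones(8)
    h2 = a2 * np.exp(-2j * np.pi * f * tau2) * np.ones(8)
    q = csi_ratio(_series(t, h1, (1, 1)), _series(t, h2, (1, 2)))
    assert np.allclose(np.abs(q.values), a1 / a2)
    expected_phase = np.angle(np.exp(-2j * np.pi * f * (tau1 - tau2)))
    assert np.allclose(np.angle(q.values), expected_phase)


def test_ratio_rejects_same_link_and_mismatched_grid():
    t = np.arange(5) / 5.0
    a = _series(t, np.ones(5), (1, 1))
    b = _series(t + 0.01, np.ones(5), (1, 2))
    with pytest.raises(ValueError):
        csi_ratio(a, a)
    with pytest.raises(ValueError):
        csi_ratio(a, b)


def test_ratio_amp_floor_marks_invalid():
    t = np.arange(6) / 5.0
    den_vals = np.array([1, 1, 1e-9, 1, 1, 1], dtype=complex)
    q = csi_ratio(
        _series(t, np.ones(6), (1, 1)),
        _series(t, den_vals, (1, 2)),
        amp_floor=1e-3,
    )
    assert not q.valid[2] and q.valid.sum() == 5
    assert np.isnan(q.values[2].real)
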