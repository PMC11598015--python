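"""Dispersion statistic and interference labelling."""

import numpy as np
import pytest

from csibreath.containers import RatioSeries
from csibreath.motion_filter import (
    DispersionSeries,
    label_interference,
    window_dispersion,
)
from csibreath.pipeline import run_pipeline
from csibreath.config import PipelineConfig
from csibreath.synthetic_csi import SimConfig, simulate_csi


def _ratio(values, num=(1, 1), den=(1, 2), sub=1):
    values = np.asarray(values, complex)
    t = np.arange(values.size) / 20.0
    return RatioSeries(
        timestamps=t, values=values, num_link=num, den_link=den, subcarrier=sub
    )


def brute_force_dispersion(ratio_lists, W, start):
    """Naive triple-loop evaluation: sum over link pairs of the
    subcarrier-averaged, (W-1)-normalised squared deviation from the
    window mean."""
    total = 0.0
    for series_list in ratio_lists:  # one list of subcarriers per pair
        acc = 0.0
        for r in series_list:
            win = [r.values[start + k] for k in range(W)]
            mean = sum(win) / W
            ssq = 0.0
            for q in win:
                ssq += abs(q - mean) ** 2
            acc += ssq / (W - 1)
        total += acc / len(series_list)
    return total


def test_dispersion_matches_bruteforce_oracle(rng):
    """Vectorised dispersion equals the naive triple loop on random data."""
    n, W, stride = 40, 5, 3
    pairs = [((1, 1), (1, 2)), ((1, 2), (1, 1))]
    series, grouped = [], []
    for num, den in pairs:
        subs = []
        for sub in (1, 2):
            v = rng.normal(size=n) + 1j * rng.normal(size=n)
            r = _ratio(v, num, den, sub)
            series.append(r)
            subs.append(r)
        grouped.append(subs)
    disp = window_dispersion(series, W, stride)
    for wi, s in enumerate(disp.window_start_idx):
        expected = brute_force_dispersion(grouped, W, int(s))
        assert disp.D[wi] == pytest.approx(expected, abs=1e-12)


def test_dispersion_two_sample_hand_value():
    # W=2, Q = {0, 2}: mean 1, deviations 1 and 1, 1/(W-1) => D = 2
    disp = window_dispersion(_ratio([0.0, 2.0]), 2)
    assert disp.D[0] == pytest.approx(2.0, abs=1e-12)


def test_dispersion_zero_for_identical_samples():
    disp = window_dispersion(_ratio(np.full(10, 1.3 - 0.2j)), 4)
    assert np.allclose(disp.D, 0.0, atol=1e-15)


def test_dispersion_rotation_invariance(rng):
    v = rng.normal(size=30) + 1j * rng.normal(size=30)
    rot = np.exp(1j * 1.234)
    d0 = window_dispersion(_ratio(v), 6).D
    d1 = window_dispersion(_ratio(v * rot), 6).D
    assert np.allclose(d0, d1, atol=1e-12)


def test_dispersion_quadratic_scaling(rng):
    v = rng.normal(size=30) + 1j * rng.normal(size=30)
    c = 3.7
    d0 = window_dispersion(_ratio(v), 5).D
    d1 = window_dispersion(_ratio(v * c), 5).D
    assert np.allclose(d1, c**2 * d0, rtol=1e-12)


def test_dispersion_outlier_cannot_decrease(rng):
    v = rng.normal(size=12) + 1j * rng.normal(size=12)
    d0 = window_dispersion(_ratio(v), 12).D[0]
    v_out = v.copy()
    v_out[5] += 10.0  # pure displacement outlier
    d1 = window_dispersion(_ratio(v_out), 12).D[0]
    assert d1 >= d0


def test_dispersion_input_validation():
    with pytest.raises(ValueError):
        window_dispersion(_ratio(np.ones(10)), 1)  # W < 2
    with pytest.raises(ValueError):
        window_dispersion(_ratio(np.ones(4)), 8)  # window > record
    same = _ratio(np.ones(10), num=(1, 1), den=(1, 1))
    with pytest.raises(ValueError):
        window_dispersion(same, 4)  # identical links inadmissible


def test_labeling_threshold():
    disp = DispersionSeries(
        window_start_times=np.array([0.0, 0.5]),
        window_start_idx=np.array([0, 10]),
        D=np.array([0.0005, 0.002]),
        window_w=10, stride=10, n_samples=20,
        links_used=[((1, 1), (1, 2))],
    )
    mask = label_interference(disp, threshold=0.001)
    assert not mask.flags[:10].any() and mask.flags[10:].all()
    clean = label_interference(disp, threshold=np.inf)
    assert not clean.flags.any()
    with pytest.raises(ValueError):
        label_interference(disp, threshold=0.0)


def test_label_gap_closing():
    disp = DispersionSeries(
        window_start_times=np.array([0.0, 0.25, 0.5]),
        window_start_idx=np.array([0, 5, 10]),
        D=np.array([0.01, 0.0, 0.01]),
        window_w=3, stride=5, n_samples=13,
        links_used=[((1, 1), (1, 2))],
    )
    open_mask = label_interference(disp, 0.001, close_gap=0)
    assert not open_mask.flags[4:10].any()
    closed = label_interference(disp, 0.001, close_gap=10)
    assert closed.flags[:13].all()


def test_burst_flagging_on_simulator_output():
    """A 2 s motion burst is flagged nearly completely while quiet
    breathing stays almost entirely clean, at default settings."""
    cfg = SimConfig(duration=60.0, seed=5, motion_bursts=((25.0, 27.0, 6.0),))
    series, truth = simulate_csi(cfg)
    out = run_pipeline(PipelineConfig(), series, truth=truth)
    t = out.ratio.timestamps
    in_burst = np.interp(t, truth.timestamps, truth.motion_mask.astype(float)) > 0.5
    assert out.mask.flags[in_burst].mean() >= 0.90
    assert out.mask.flags[~in_burst].mean() <= 0.05
    # dispersion ordering: motion windows disperse far more than quiet ones
    from csibreath.motion_filter import window_dispersion as wd

    disp = wd([out.ratio], 3, 1)
    wt = disp.window_start_times
    motion = (wt >= 25.0) & (wt < 27.0)
    assert np.median(disp.D[motion]) > 10 * np.median(disp.D[~motion])
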