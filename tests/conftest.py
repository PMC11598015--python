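import numpy as np
import pytest

from csibreath import PipelineConfig, SimConfig, simulate_csi
from csibreath.pipeline import run_pipeline


@pytest.fixture(scope="session")
def quiet_run():
    """One 60 s quiet-breathing record at defaults, pipeline output included."""
    cfg = SimConfig(duration=60.0, seed=0)
    series, truth = simulate_csi(cfg)
    out = run_pipeline(PipelineConfig(), series, truth=truth)
    return cfg, series, truth, out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
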