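import numpy as np
import pytest

from svquant import DetectionParams, FluorescenceTrace, TraceSimConfig, simulate_trace


@pytest.fixture
def default_params() -> DetectionParams:
    return DetectionParams()


@pytest.fixture
def high_snr_cfg() -> TraceSimConfig:
    """Bright events (quantal mean 10x the noise SD) for detector checks."""
    return TraceSimConfig(
        duration=600.0,
        spont_rate=0.5,
        amp_mean=2120.0,
        amp_sd=200.0,
        noise_sd=212.0,
        n_rois=8,
        seed=42,
    )


@pytest.fixture
def high_snr_data(high_snr_cfg):
    return simulate_trace(high_snr_cfg)


@pytest.fixture
def noise_trace() -> FluorescenceTrace:
    """Pure Gaussian noise around a realistic baseline, no events."""
    rng = np.random.default_rng(7)
    return FluorescenceTrace(
        "noise", 0.12, 16400.0 + rng.normal(0, 212.0, 5000)
    )
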