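import numpy as np
import pytest

from invisible_ecg import FilterSpec, SynthConfig, design_bandpass, generate_pair


@pytest.fixture(scope="session")
def taps_1khz():
    return design_bandpass(FilterSpec(), 1000.0)


@pytest.fixture(scope="session")
def clean_pair():
    """Noise-free pair: experimental channel is a delayed copy of the reference."""
    cfg = SynthConfig(
        duration=120.0, seed=5, noise_rms=0.0, wander_amp=0.0,
        sat_rate=0.0, sync_offset=300,
    )
    return cfg, generate_pair(cfg)


@pytest.fixture(scope="session")
def noisy_pair():
    """Default-noise 5-min pair, the study-like condition."""
    cfg = SynthConfig(duration=300.0, seed=11)
    return cfg, generate_pair(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
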