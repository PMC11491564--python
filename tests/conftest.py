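import numpy as np
import pytest

from ecgredund import (
    BinningConfig,
    DipoleParams,
    MultichannelRecord,
    bin_record,
    simulate_12lead,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_record():
    """A deterministic 8-sample, 3-channel record with a rich bin pattern."""
    data = np.array(
        [
            [0.1, 0.1, 0.9],
            [0.6, 0.6, 0.1],
            [1.1, 0.1, 0.6],
            [0.1, 0.6, 0.1],
            [0.6, 0.1, 1.2],
            [0.1, 0.1, 0.1],
            [1.1, 0.6, 0.6],
            [0.6, 0.6, 0.9],
        ]
    )
    return MultichannelRecord(("A", "B", "C"), data, 500.0)


@pytest.fixture
def tiny_binned(tiny_record):
    return bin_record(tiny_record, BinningConfig(bin_width_mv=0.5))


@pytest.fixture(scope="session")
def clean_12lead():
    """Noise-free, jitter-free synthetic 12-lead record (pure dipole)."""
    params = DipoleParams(seed=21, noise_sd_mv=0.0, electrode_jitter_deg=0.0)
    return simulate_12lead(params)


@pytest.fixture(scope="session")
def noisy_12lead_long():
    """A 100-s noisy 12-lead record for estimator-level properties."""
    params = DipoleParams(seed=7, duration_s=100.0)
    return simulate_12lead(params)
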