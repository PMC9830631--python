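import numpy as np
import pytest

from csibreathe import ChannelConfig, NoiseConfig, PATTERN_TABLE, simulate_csi
from csibreathe.fixtures import _two_class_dataset
from csibreathe.experiments import ExperimentSpec


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale channel: 2x1 antennas, 8 subcarriers, 15 s at 10 Hz."""
    return ChannelConfig(n_subcarriers=8, n_tx=1, n_rx=2, duration_s=15.0)


@pytest.fixture(scope="session")
def normal_tensor_small(small_cfg):
    """Normal breathing (15 BPM) at the desk-scale channel, 30 dB SNR."""
    return simulate_csi(PATTERN_TABLE[6], small_cfg, NoiseConfig(seed=7))


@pytest.fixture(scope="session")
def mini_dataset():
    """Two-class feature dataset (patterns #2 vs #4, 20 streams each)."""
    spec = ExperimentSpec(task="pattern-9", n_subcarriers=8, n_tx=1, n_rx=2,
                          duration_s=15.0, seed=3)
    return _two_class_dataset(spec, n_per_class=20)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
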