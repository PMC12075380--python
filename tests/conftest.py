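import numpy as np
import pytest

from tgcwm.montage import RegionMap
from tgcwm.synth import SynthConfig

TWO_CHANNELS = ("F3", "O1")
TWO_REGIONS = {"left_frontal": ("F3",), "left_occipital": ("O1",)}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Fast, low-rate synthetic session: 6-channel montage, 250 Hz."""
    return SynthConfig(
        sampling_rate=250.0,
        channel_names=("F3", "F5", "F7", "P7", "PO7", "O1"),
        n_trials_per_condition=4,
        pink_sd=1.0,
        noise_sd=0.5,
        seed=11,
    )


@pytest.fixture
def clean_config():
    """Noise-free two-channel config for closed-form checks."""
    return SynthConfig(
        sampling_rate=500.0,
        channel_names=TWO_CHANNELS,
        n_trials_per_condition=2,
        pink_sd=0.0,
        noise_sd=0.0,
        seed=5,
    )


@pytest.fixture
def two_region_map():
    return RegionMap(TWO_REGIONS, montage=TWO_CHANNELS)
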