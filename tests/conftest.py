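import numpy as np
import pytest

from gyrowave import (GyroSpec, RecordingProtocol, build_dataset, get_wavelet)


@pytest.fixture(scope="session")
def default_dataset():
    """The full study-protocol synthetic dataset: 8 motions x 8 intervals
    x 6 segments of 1,600 samples on 2 channels, SNR 20 dB, seed 1."""
    return build_dataset(seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced recording (3 intervals x 3 x 800-sample segments per
    motion) for experiments that only need a trainable dataset."""
    protocol = RecordingProtocol(intervals_per_motion=3, interval_s=18.0,
                                 segments_per_interval=3, segment_len=800)
    return build_dataset(protocol, seed=3)


@pytest.fixture(scope="session")
def rbio31():
    return get_wavelet("reverse_biorthogonal", "3.1")


@pytest.fixture(scope="session")
def haar():
    return get_wavelet("haar")


@pytest.fixture
def default_spec():
    return GyroSpec()
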