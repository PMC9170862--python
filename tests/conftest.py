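import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def fs():
    return 128.0


def make_recording(duration_s=120.0, fs=128.0, seed=0, **kwargs):
    """Plain white-noise recording helper for I/O and windowing tests."""
    from ewtdoa.io import EEGRecording

    gen = np.random.default_rng(seed)
    n = int(duration_s * fs)
    return EEGRecording(samples=gen.standard_normal(n), fs=fs, **kwargs)
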