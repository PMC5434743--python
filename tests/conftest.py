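import numpy as np
import pytest

import cortconn.forward as fwd
from cortconn.inverse import CLoretaSolver


@pytest.fixture(scope="session")
def small_model():
    """Coarse head model (162 gridpoints, 32 electrodes) for fast unit tests."""
    return fwd.build_default_head_model(subdivisions=2, n_electrodes=32)


@pytest.fixture(scope="session")
def mid_model():
    """Default-resolution head model (642 gridpoints, 64 electrodes)."""
    return fwd.build_default_head_model(subdivisions=3, n_electrodes=64)


@pytest.fixture(scope="session")
def small_solver(small_model):
    return CLoretaSolver(small_model.K, small_model.H_lap)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_eeg():
    """Tiny deterministic epoched recording: 4 channels, 64 samples, 6 trials."""
    from cortconn.io import EpochedEEG

    gen = np.random.default_rng(7)
    data = gen.standard_normal((4, 64, 6)) * 10.0
    pos = gen.standard_normal((4, 3)) * 0.05
    return EpochedEEG(
        data=data,
        fs=128.0,
        channel_names=["C1", "C2", "C3", "C4"],
        channel_pos=pos,
        condition=np.array(["control"] * 3 + ["test"] * 3, dtype=object),
        epoch_window=(0.0, 0.5),
    )
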