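"""Shared fixtures: synthetic recordings with known ground truth.

Everything is generated at test time from seeded generators; the
generator parameters are the ground truth the tests assert against.
"""

import numpy as np
import pytest

from lfpac.io import ChannelSignal, Recording
from lfpac.synth import PacSpec, make_pac_signal, make_stim_recording

FS = 1000.0


@pytest.fixture(scope="session")
def coupled_sig() -> ChannelSignal:
    """Standard theta-gamma coupled fixture: 8 Hz phase modulating 80 Hz."""
    return make_pac_signal(PacSpec(duration=30.0, depth=0.7, snr=3.0, seed=2))


@pytest.fixture(scope="session")
def coupled_spec() -> PacSpec:
    return PacSpec(duration=30.0, depth=0.7, snr=3.0, seed=2)


@pytest.fixture(scope="session")
def stim_recording():
    """10-pulse, 3 s ISI recording with a noiseless evoked response."""
    return make_stim_recording(fs=FS, n_trials=10, isi=3.0, noise_sd=0.0, seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def white_recording(rng) -> Recording:
    """2-channel white-noise recording, 10 s at 1 kHz."""
    return Recording(rng.standard_normal((2, 10_000)), FS,
                     ["sig", "stim"], ["mV", "mV"])
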