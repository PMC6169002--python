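import numpy as np
import pytest

from cmcoupling import (
    StimProtocol,
    SynthConfig,
    gen_cmc_recording,
    preprocess_recording,
    segment_trials,
)


@pytest.fixture(scope="session")
def protocol():
    return StimProtocol(ntb=250)


@pytest.fixture(scope="session")
def small_recording(protocol):
    """A short pre-stimulation synthetic recording (6 trials, seed 3)."""
    cfg = SynthConfig(n_trials=6, seed=3)
    return gen_cmc_recording(protocol, cfg, phase="pre")


@pytest.fixture(scope="session")
def preprocessed_trials(small_recording, protocol):
    """Pre/post trial sets of the conditioned small recording."""
    prep = preprocess_recording(small_recording)
    return segment_trials(prep, 1.0, 1.0, protocol)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
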