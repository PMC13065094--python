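import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from samph import (CarrierSpec, default_chain, design_bank, gen_modulator_chain,
                   gen_utterance, pad_ends, znormalize)
from samph.reference import REFERENCE_SPECTRAL_BANDS


@pytest.fixture(scope="session")
def spectral_bank():
    return design_bank(100.0, 7250.0, 28, "erb_n")


@pytest.fixture(scope="session")
def mod_bank():
    return design_bank(0.9, 40.0, 24, "log")


@pytest.fixture(scope="session")
def reference_spectral_bands():
    return REFERENCE_SPECTRAL_BANDS


@pytest.fixture(scope="session")
def small_audio_corpus():
    """Six preprocessed pseudo-speech files with modulators at 1.5/7/30 Hz."""
    files = []
    for seed in range(6):
        chain = gen_modulator_chain(default_chain(), 12.0, 240.0, seed=seed)
        sf = gen_utterance(CarrierSpec(), chain, seed=seed)
        files.append(znormalize(pad_ends(sf, 3.0)))
    return files


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
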