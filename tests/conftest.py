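import numpy as np
import pytest

from wavemos import (DegradationSpec, FeatureConfig, align_pair, degrade,
                     make_benchmark, synth_utterance)


@pytest.fixture(scope="session")
def simple_wave():
    return synth_utterance("simple", duration=1.5, seed=11)


@pytest.fixture(scope="session")
def complex_wave():
    return synth_utterance("complex", duration=1.5, seed=11)


@pytest.fixture(scope="session")
def identity_pair(complex_wave):
    return align_pair(complex_wave, complex_wave, trial_id="ident")


@pytest.fixture(scope="session")
def noisy_pair(complex_wave):
    rec = degrade(complex_wave, DegradationSpec(noise_sd=0.2, seed=5))
    return align_pair(complex_wave, rec, trial_id="noisy")


@pytest.fixture(scope="session")
def config():
    return FeatureConfig()


@pytest.fixture(scope="session")
def small_study():
    """A small multi-dataset study shared by validation/CLI tests."""
    return make_benchmark(n_datasets=4, trials_per_dataset=4, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
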