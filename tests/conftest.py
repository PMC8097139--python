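import numpy as np
import pytest

from stomgeo import generate_study_preset
from stomgeo.synth import SynthConfig, generate_traits


@pytest.fixture(scope="session")
def study_preset_data():
    """A 300-species synthetic table plus matching tree (fixed seed)."""
    return generate_study_preset(seed=1)


@pytest.fixture(scope="session")
def table(study_preset_data):
    return study_preset_data[0]


@pytest.fixture(scope="session")
def phylo(study_preset_data):
    return study_preset_data[1]


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def noiseless_config(seed=0, **overrides):
    kwargs = dict(
        si_noise_sd=0.0, es_noise_sd=0.0, sd_noise_sd=0.0, seed=seed
    )
    kwargs.update(overrides)
    return SynthConfig(**kwargs)


@pytest.fixture
def noiseless_table():
    return generate_traits(noiseless_config())
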