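import numpy as np
import pytest

from echoclr.fixtures import FixtureConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-study cohort with a large planted effect, shared across tests."""
    config = FixtureConfig(n_studies=20, frame_size=64, frames_per_video=16,
                           prevalence=0.5, seed=11)
    manifest, videos = generate_cohort(config)
    return config, manifest, videos


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
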