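import numpy as np
import pytest

from soc_sft import WorldConfig, generate_world
from soc_sft.grouping import environments_frame
from soc_sft.pipeline import prepare_profiles


@pytest.fixture(scope="session")
def small_world():
    """A modest synthetic world shared by read-only tests."""
    return generate_world(WorldConfig(n_profiles=600, seed=11))


@pytest.fixture(scope="session")
def clean_world():
    """Noise-free, fully observed world: downstream estimates hit the analytic law."""
    return generate_world(WorldConfig(
        n_profiles=800, seed=5, noise_cv=0.0,
        missing_bd_rate=0.0, missing_gravel_rate=0.0, cropland_rate=0.0))


@pytest.fixture(scope="session")
def small_harmonized(small_world):
    return prepare_profiles(small_world.profiles, small_world.environments, seed=11)


@pytest.fixture(scope="session")
def small_env_frame(small_world):
    return environments_frame(small_world.environments)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
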