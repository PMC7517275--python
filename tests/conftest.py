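import numpy as np
import pytest

from drstissue import (
    DesignConfig,
    default_grid,
    default_tissue_profiles,
    generate_dataset,
)


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def profiles():
    return default_tissue_profiles()


@pytest.fixture(scope="session")
def small_design():
    # 5 tissues x 2 specimens x 1 sample x 2 points x 2 measurements = 40
    return DesignConfig(n_specimens=2, n_samples_per_specimen=1,
                        n_points=2, n_measurements=2, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_design, profiles):
    return generate_dataset(small_design, profiles)


@pytest.fixture(scope="session")
def noiseless_profiles(profiles):
    return {name: p.noiseless() for name, p in profiles.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
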