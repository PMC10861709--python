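import numpy as np
import pytest

from rbp.channel_systems import project_to_2d
from rbp.synthetic import SyntheticDatasetSpec, generate_montage_family


@pytest.fixture(scope="session")
def montage_family():
    """Deterministic 129/65/32 nested synthetic montage family."""
    return generate_montage_family(SyntheticDatasetSpec(n_subjects=4))


@pytest.fixture(scope="session")
def base_system(montage_family):
    return montage_family["synthetic129"]


@pytest.fixture(scope="session")
def sys65(montage_family):
    return montage_family["synthetic65"]


@pytest.fixture(scope="session")
def sys32(montage_family):
    return montage_family["synthetic32"]


@pytest.fixture(scope="session")
def projected_base(base_system):
    return project_to_2d(base_system)


@pytest.fixture(scope="session")
def projected_32(sys32):
    return project_to_2d(sys32)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
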