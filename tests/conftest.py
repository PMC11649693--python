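import numpy as np
import pytest
from hypothesis import settings

import nearfall as nf

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def profile():
    """One fixed subject profile used across tests."""
    return nf.GaitProfile(seed=1)


@pytest.fixture(scope="session")
def baselines(profile):
    return [nf.generate_baseline(profile, seed=profile.seed + 101 + j) for j in range(3)]


@pytest.fixture(scope="session")
def thresholds(baselines):
    return nf.calibrate(baselines)


@pytest.fixture(scope="session")
def references(thresholds):
    return nf.TaskReference.from_thresholds(thresholds)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
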