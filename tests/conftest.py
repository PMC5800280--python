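import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import neurogait as ng
from neurogait.blocks import NoiseSpec

settings.register_profile(
    "default", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def paradigm():
    """The walking protocol: 10 x (10 s walk + 20 s rest), 30 s lead-in/out,
    1.81 Hz sampling."""
    return ng.default_paradigm()


@pytest.fixture(scope="session")
def montage():
    return ng.default_montage()


@pytest.fixture(scope="session")
def subject_blocks(paradigm, montage):
    """One synthetic subject at the default contrast (HbO, HbR)."""
    return ng.simulate_hbo(paradigm, montage, 1.0, NoiseSpec(seed=7))


@pytest.fixture(scope="session")
def hbo_block(subject_blocks):
    return subject_blocks[0]


@pytest.fixture(scope="session")
def hrf_features(paradigm, hbo_block):
    """HRF-smoothed, averaged, windowed features for the synthetic subject."""
    filt = ng.apply_filter(hbo_block, ng.FilterSpec(method="hrf"))
    return ng.extract_features(ng.spatial_average(filt), paradigm)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
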