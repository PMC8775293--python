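import numpy as np
import pytest

from iolglare import RunConfig, build_model


@pytest.fixture(scope="session")
def model6():
    return build_model(6, "standard")


@pytest.fixture(scope="session")
def model7():
    return build_model(7, "standard")


@pytest.fixture(scope="session")
def model6_thin():
    return build_model(6, "thin")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    """Reduced ray budget for fast experiment-level tests."""
    return RunConfig(rays_per_angle=6000)
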