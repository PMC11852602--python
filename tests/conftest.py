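import numpy as np
import pytest

from osteostim import FemurFixtureParams, generate_block_fixture
from osteostim.analysis import build_study


@pytest.fixture
def block_mesh():
    return generate_block_fixture(3, 3, 3, (10.0, 10.0, 10.0))


@pytest.fixture(scope="session")
def coarse_femur_params():
    """Small femur used by unit tests (fast to mesh and solve)."""
    return FemurFixtureParams(target_element_count=3000)


@pytest.fixture(scope="session")
def femur_study():
    """Full intact/implanted study pipeline on the default-size fixture.

    Session-scoped: static solves for three load cases on two meshes plus
    the electrostatic solve are shared by the analysis and acceptance tests.
    """
    return build_study(FemurFixtureParams(target_element_count=6000))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
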