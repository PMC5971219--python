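import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def coarse_mesh():
    """Small labeled slab used by geometry and optics unit tests."""
    from babydcm.mesh import build_layered_slab_mesh

    return build_layered_slab_mesh((40.0, 40.0, 30.0), (5.0, 2.0, 23.0), 10.0)


@pytest.fixture(scope="session")
def fixture_array():
    from babydcm.mesh import build_fixture_array

    return build_fixture_array()


@pytest.fixture(scope="session")
def homogeneous_coeffs():
    """Single-tissue optics (oracle comparisons)."""
    from babydcm.optics import OpticalCoefficients

    table = {(label, 770.0): (0.01, 1.0) for label in (1, 2, 3)}
    return OpticalCoefficients(table, A_boundary=2.82)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20181507)
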