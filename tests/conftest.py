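import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from adfsi.coupling import CannulationScenario, run_fsi
from adfsi.geometry import build_reduced_ad_geometry, generate_meshes
from adfsi.materials import ElasticConstants, neo_hookean_from_elastic


@pytest.fixture(scope="session")
def reduced_spec():
    return build_reduced_ad_geometry()


@pytest.fixture(scope="session")
def reduced_meshes(reduced_spec):
    return generate_meshes(reduced_spec, level=1)


@pytest.fixture(scope="session")
def nh_shore20a():
    """Neo-Hookean parameters for the Shore-20A flap (E = 0.732 MPa)."""
    return neo_hookean_from_elastic(ElasticConstants(0.732, 0.49))


@pytest.fixture(scope="session")
def nh_soft():
    """The softer comparison flap (E = 0.1 MPa)."""
    return neo_hookean_from_elastic(ElasticConstants(0.1, 0.49))


@pytest.fixture(scope="session")
def coupled_sweep(reduced_meshes, nh_shore20a):
    """Shared coupled-run cache: (mode, nominal flow) -> SimulationResult for
    the Shore-20A flap on the reduced geometry."""
    out = {}
    for mode in ("AC", "AFC"):
        for q in (3.0, 5.0, 7.0):
            out[(mode, q)] = run_fsi(
                reduced_meshes, CannulationScenario(mode, q), nh_shore20a
            )
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230120)
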