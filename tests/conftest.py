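import numpy as np
import pytest
from hypothesis import settings

from recimeg.bem import ChargeOperator
from recimeg.geometry import ConductivityLayer, HeadModel, build_icosphere

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sphere_head():
    """Single conducting sphere, 320 faces, moderate contrast."""
    mesh = build_icosphere(0.08, 2)
    return HeadModel([ConductivityLayer(mesh, 0.33, 0.0, "scalp")])


@pytest.fixture(scope="session")
def two_sphere_head():
    """Two nested spheres, 400 faces total, skin/skull-like contrast."""
    outer = build_icosphere(0.09, 2)
    inner = build_icosphere(0.07, 1)
    return HeadModel([
        ConductivityLayer(outer, 0.25, 0.0, "skin"),
        ConductivityLayer(inner, 0.01, 0.25, "skull"),
    ])


@pytest.fixture(scope="session")
def two_sphere_operator(two_sphere_head):
    return ChargeOperator(two_sphere_head)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
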