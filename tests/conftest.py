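import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import overbook as ob
from overbook.synthetic import DEFAULT_HOLIDAYS, SyntheticPopulationSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def case_study():
    return ob.default_case_study_config()


@pytest.fixture(scope="session")
def synthetic_draw():
    """Full-size synthetic draw (one per session), with derived variables."""
    raw = ob.generate_bookings(SyntheticPopulationSpec(seed=2024))
    return ob.derive_features(raw, holidays=DEFAULT_HOLIDAYS)


@pytest.fixture(scope="session")
def small_draw():
    """Quarter-size draw for faster pipeline tests."""
    raw = ob.generate_bookings(SyntheticPopulationSpec(seed=11).scaled(0.25))
    return ob.derive_features(raw, holidays=DEFAULT_HOLIDAYS)


def two_resource_config(prices=(10.0, 10.0), K=(1, 1), U=(0, 0)):
    """Tiny center: two sets, two resources, diagonal V."""
    return ob.CenterConfig(
        sets=tuple(
            ob.ExaminationSet(f"s{j}", p, 0) for j, p in enumerate(prices)
        ),
        resources=tuple(
            ob.Resource(f"r{i}", k, u) for i, (k, u) in enumerate(zip(K, U))
        ),
        matrix=ob.SetResourceMatrix(np.eye(len(prices), dtype=int)),
    )


@pytest.fixture
def tiny_config():
    return two_resource_config()
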