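import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from flowscope.network_builder import build_impedance, build_thiessen
from flowscope.synthetic_city import CityConfig, generate_city

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_city():
    """20 hospitals, 4 districts: fast enough for per-test null simulations."""
    return generate_city(CityConfig(seed=11, n_hospitals_by_grade=(10, 6, 4), n_districts=4))


@pytest.fixture(scope="session")
def small_units(small_city):
    return build_thiessen(small_city.hospitals, small_city.study_area)


@pytest.fixture(scope="session")
def small_R(small_units, small_city):
    return build_impedance(small_units, small_city.hospitals, n_samples=100, seed=2)


@pytest.fixture(scope="session")
def medium_city():
    """50 hospitals, 5 districts: used for parameter-recovery experiments."""
    return generate_city(CityConfig(seed=3, n_hospitals_by_grade=(25, 15, 10), n_districts=5))


@pytest.fixture(scope="session")
def medium_units(medium_city):
    return build_thiessen(medium_city.hospitals, medium_city.study_area)


@pytest.fixture(scope="session")
def medium_R(medium_units, medium_city):
    return build_impedance(medium_units, medium_city.hospitals, n_samples=300, seed=1)
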