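import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from harvstat.model import StatSeries
from harvstat.synthetic import ScenarioConfig, make_scenario

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def yield_series():
    """Factory: a StatSeries with the given yields (NaN = missing)."""

    def make(values, years=None, production=None, area=None, key=None):
        values = np.asarray(values, dtype=float)
        n = len(values)
        years = np.arange(2000, 2000 + n) if years is None else np.asarray(years)
        production = np.full(n, np.nan) if production is None else production
        area = np.full(n, np.nan) if area is None else area
        return StatSeries(
            key=key or ("SY2000A201", "maize", "annual", "none"),
            years=years,
            production=production,
            area=area,
            yields=values,
        )

    return make


@pytest.fixture(scope="session")
def split_scenario():
    return make_scenario(ScenarioConfig(seed=11, boundary_event="split"))


@pytest.fixture(scope="session")
def reorganize_scenario():
    return make_scenario(ScenarioConfig(seed=12, boundary_event="reorganize"))


@pytest.fixture(scope="session")
def plain_scenario():
    return make_scenario(ScenarioConfig(seed=13))
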