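import importlib.resources

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from birdrisk.synth import ScenarioConfig, generate_scenario

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scenario():
    """Medium multi-airbase scenario shared across tests (seeded)."""
    return generate_scenario(
        ScenarioConfig(seed=7, n_airbases=3, n_species=15, years=3)
    )


@pytest.fixture(scope="session")
def noise_free_scenario():
    """Scenario whose observer statuses carry no label noise."""
    return generate_scenario(
        ScenarioConfig(seed=11, n_airbases=2, n_species=10, years=2, observer_noise=0.0)
    )


@pytest.fixture(scope="session")
def airbase_summary_rows():
    """Bundled per-airbase monitoring summary (six-airbase programme)."""
    path = importlib.resources.files("birdrisk").joinpath(
        "data/rnlaf_airbase_summary.csv"
    )
    with path.open() as fh:
        return pd.read_csv(fh)
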