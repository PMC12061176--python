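import numpy as np
import pytest

from ems_access import CityConfig, RunConfig, generate_city, run_all
from ems_access.access_surface import InterpConfig


@pytest.fixture(scope="session")
def small_city():
    """A compact two-period city shared by read-only tests."""
    return generate_city(
        CityConfig(
            seed=3,
            n_rows=20,
            n_cols=20,
            n_stations=5,
            n_districts=4,
            n_central_districts=2,
            congestion={"00:00": 1.0, "18:00": 0.65},
        )
    )


@pytest.fixture(scope="session")
def small_run_config():
    return RunConfig(
        city=CityConfig(
            seed=5,
            n_rows=24,
            n_cols=24,
            n_stations=6,
            n_districts=4,
            n_central_districts=2,
            congestion={"00:00": 1.0, "18:00": 0.65},
        ),
        interp=InterpConfig(n_neighbors=12),
    )


@pytest.fixture(scope="session")
def small_run(small_run_config):
    """One full pipeline run shared by the pipeline/consistency tests."""
    return run_all(small_run_config)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
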