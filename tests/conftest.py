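import numpy as np
import pytest

from otolife.config import IsoscapeConfig, SimConfig
from otolife.simulate import simulate_cohort


@pytest.fixture(scope="session")
def iso():
    return IsoscapeConfig()


@pytest.fixture(scope="session")
def iso_noiseless():
    return IsoscapeConfig(measurement_sd=0.0)


@pytest.fixture(scope="session")
def wild_cohort(iso):
    """One all-wild cohort shared across tests (seeded, 4000 fish)."""
    cfg = SimConfig(n_fish=4000, hatchery_fraction=0.0, seed=11)
    histories, profiles, records = simulate_cohort(cfg, iso, rng=np.random.default_rng(11))
    return cfg, histories, profiles, records
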