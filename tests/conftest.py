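import sys
from datetime import date
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from isoroot.mixing_model import MCMCSettings
from isoroot.synthetic_data import SimConfig, emit_observations, generate_season


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def default_truth(default_config):
    """Full default-length season, shared across tests (read-only)."""
    return generate_season(default_config)


@pytest.fixture(scope="session")
def default_obs(default_truth):
    return emit_observations(default_truth)


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """Short season for end-to-end pipeline tests."""
    return SimConfig(
        season_start=date(2018, 6, 1),
        season_end=date(2018, 7, 10),
        drought_window=(date(2018, 6, 12), date(2018, 7, 2)),
        seed=7,
    )


@pytest.fixture()
def fast_mcmc() -> MCMCSettings:
    """Reduced chains: larger Monte-Carlo error, same target distribution."""
    return MCMCSettings(chain_length=6000, burn_in=3000, thin=3, n_chains=3, seed=42)
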