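import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from metophos.ptm_tables import (ModSite, ProteinRecord, ProteinSet,
                                 SiteTable)
from metophos.synthetic_data import SimConfig, simulate_proteome

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_proteins() -> ProteinSet:
    return ProteinSet([
        ProteinRecord("P1", "MKSAYSTMKA", abundance=100.0),
        ProteinRecord("P2", "AAASMMTYKA"),
    ])


@pytest.fixture
def toy_sites(toy_proteins) -> SiteTable:
    return SiteTable.from_sites([
        ModSite("P1", 3, "S", "phospho"),
        ModSite("P1", 8, "M", "sulfoxide", oxidized_fraction=0.5),
        ModSite("P2", 7, "T", "phospho"),
        ModSite("P2", 5, "M", "sulfoxide", oxidized_fraction=0.3),
        ModSite("P2", 9, "K", "ubiquityl"),
    ])


@pytest.fixture(scope="session")
def sim_default():
    """One moderately sized neutral simulated proteome shared across tests."""
    config = SimConfig(n_proteins=250, seed=42)
    return simulate_proteome(config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230917)
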