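import numpy as np
import pytest

from ecbs.evoann import catalog_from_records
from ecbs.synth import UniverseConfig, simulate_universe


@pytest.fixture(scope="session")
def universe():
    """Default synthetic chemogenomic universe (shared, read-only)."""
    return simulate_universe(UniverseConfig(seed=7))


@pytest.fixture(scope="session")
def small_universe():
    """Smaller universe for fast training tests."""
    return simulate_universe(UniverseConfig(
        seed=3, targets_per_family=2, actives_per_target=10,
        background_molecules=150,
    ))


@pytest.fixture()
def kinase_catalog():
    """Hand-built annotation catalog: two families inside one superfamily,
    one unrelated outlier target."""
    return catalog_from_records(
        [
            ("MEK1", "family", "STE7"),
            ("MEK2", "family", "STE7"),
            ("MEK1", "superfamily", "STE"),
            ("MEK2", "superfamily", "STE"),
            ("PAK1", "family", "STE20"),
            ("PAK1", "superfamily", "STE"),
            ("EPHB4", "family", "EPH"),
            ("EPHB4", "superfamily", "TK"),
        ],
        levels=("motif", "domain", "family", "superfamily"),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
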