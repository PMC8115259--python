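import numpy as np
import pandas as pd
import pytest

from dualcore.datatypes import AbundanceTable, GenomeContentTable
from dualcore.synthetic import SyntheticScenario, generate_scenario


@pytest.fixture
def small_table() -> AbundanceTable:
    data = pd.DataFrame(
        [[1, 0, 3, 2], [2, 3, 0, 0], [0, 0, 0, 5], [4, 4, 4, 4]],
        index=["a1", "a2", "a3", "a4"],
        columns=["s1", "s2", "s3", "s4"],
        dtype=float,
    )
    meta = pd.DataFrame(
        {"study": "t", "habitat": ["H1", "H1", "H2", "H2"], "group": "g"},
        index=data.columns,
    )
    return AbundanceTable(data, metadata=meta)


@pytest.fixture
def identity_gc() -> GenomeContentTable:
    """Each ASV carries exactly one private KO with copy 1 and one 16S copy."""
    asvs = ["a1", "a2", "a3", "a4"]
    kos = [f"K_{a}" for a in asvs]
    mat = pd.DataFrame(np.eye(4, dtype=int), index=asvs, columns=kos)
    return GenomeContentTable(ko_copies=mat, ssu_copies=pd.Series(1, index=asvs))


@pytest.fixture(scope="session")
def default_scenario():
    config = SyntheticScenario(seed=11)
    return config, generate_scenario(config)


@pytest.fixture(scope="session")
def noise_free_scenario():
    config = SyntheticScenario(
        n_samples=30,
        core_prevalence=1.0,
        background_prevalence=0.0,
        overdispersion=float("inf"),
        sequencing_depth_mean=100_000,
        habitat_effect=0.0,
        seed=5,
    )
    return config, generate_scenario(config)
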