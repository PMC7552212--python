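import numpy as np
import pytest

from strpop import GenotypeTable, LocusMeta, SimulationConfig, simulate_table


@pytest.fixture
def tiny_table() -> GenotypeTable:
    """Two populations, two loci, hand-writable genotypes."""
    calls = np.array(
        [
            [[101, 103], [200, 200]],
            [[101, 101], [200, 202]],
            [[103, 103], [202, 202]],
            [[101, 103], [200, 202]],
        ]
    )
    return GenotypeTable(
        individuals=["a1", "a2", "b1", "b2"],
        populations=["A", "A", "B", "B"],
        loci=[LocusMeta("L1"), LocusMeta("L2")],
        calls=calls,
    )


@pytest.fixture(scope="session")
def study_table() -> GenotypeTable:
    """Seeded table drawn under the six-sire-line study design."""
    return simulate_table(SimulationConfig(), seed=202)


@pytest.fixture(scope="session")
def two_cluster_table() -> GenotypeTable:
    """Two well-differentiated populations for clustering checks."""
    cfg = SimulationConfig(
        pop_sizes=(20, 20), pop_names=("A", "B"), n_loci=10,
        x_linked_index=None, fst=0.3,
    )
    return simulate_table(cfg, seed=5)
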