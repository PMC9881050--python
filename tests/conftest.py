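import numpy as np
import pytest
from hypothesis import settings

import targetrank as tr

settings.register_profile("repro", derandomize=True, max_examples=50)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_genome():
    """A compact synthetic genome shared across tests (deterministic)."""
    return tr.generate_genome(tr.GeneratorConfig(n_proteins=400, n_positives=40, seed=11))


@pytest.fixture(scope="session")
def small_matrix(small_genome):
    return small_genome.feature_matrix()


@pytest.fixture(scope="session")
def small_gold(small_genome):
    return tr.build_gold_standard(
        small_genome.positives,
        small_genome.protein_ids,
        size=40,
        n_replicates=5,
        seed=5,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
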