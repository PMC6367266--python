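import numpy as np
import pytest

from cfrp import (
    KmerConfig,
    SyntheticConfig,
    make_worked_micro_example,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def micro_dataset():
    return make_worked_micro_example()


@pytest.fixture(scope="session")
def small_synthetic():
    """A small planted-signal dataset for fast pipeline tests."""
    config = SyntheticConfig(
        n_rna=70,
        n_protein=70,
        rna_length=(80, 120),
        protein_length=(120, 200),
        n_positive=60,
        n_negative=60,
        seed=11,
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def kmer22():
    return KmerConfig(m=2, n=2)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
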