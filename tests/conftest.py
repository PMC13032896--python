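import numpy as np
import pytest

from udpep.peptide_space import index_to_peptide


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def random_tetrapeptides(rng):
    """2000 distinct random tetrapeptides (seeded draw from the space)."""
    idx = rng.choice(20**4, size=2000, replace=False)
    return [index_to_peptide(int(i), 4) for i in idx]


@pytest.fixture(scope="session")
def small_synthetic(random_tetrapeptides):
    """Default planted-model dataset on the random sample."""
    from udpep.synthetic_data import generate_dataset

    return generate_dataset(random_tetrapeptides, seed=7)
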