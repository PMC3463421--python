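import numpy as np
import pytest

from epiforest.gensim import GenotypeMatrix, simulate_independent_genotypes


@pytest.fixture(scope="session")
def strong_signal_data():
    """Small dataset with one strongly predictive SNP (index 3) among 10."""
    G = simulate_independent_genotypes(300, [0.3] * 10, seed=11)
    rng = np.random.default_rng(12)
    y = ((G.values[:, 3] + rng.normal(0, 0.8, 300)) > 0.5).astype(np.int8)
    return G, y


@pytest.fixture(scope="session")
def null_data():
    """Labels independent of genotypes, balanced classes."""
    G = simulate_independent_genotypes(400, [0.3] * 12, seed=21)
    y = np.zeros(400, dtype=np.int8)
    y[np.random.default_rng(22).permutation(400)[:200]] = 1
    return G, y


def make_genotypes(values, mafs=None):
    values = np.asarray(values, dtype=np.int8)
    if mafs is None:
        mafs = np.full(values.shape[1], 0.3)
    return GenotypeMatrix(values=values, mafs=np.asarray(mafs, dtype=float))
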