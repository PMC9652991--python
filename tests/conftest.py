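import numpy as np
import pytest

from spinypop.genotype_io import MISSING, GenotypeMatrix


def random_matrix(n_ind=10, n_loci=20, n_pops=2, missing_rate=0.05, seed=0):
    """Small random genotype matrix with HW-ish genotypes and missing calls."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, n_loci)
    calls = rng.binomial(2, p, size=(n_ind, n_loci)).astype(np.int16)
    calls[rng.random((n_ind, n_loci)) < missing_rate] = MISSING
    ids = [f"ind{i:02d}" for i in range(n_ind)]
    pops = {ind: f"pop{i % n_pops}" for i, ind in enumerate(ids)}
    return GenotypeMatrix(ids, [f"L{j}" for j in range(n_loci)], calls, pops)


@pytest.fixture
def small_matrix():
    return random_matrix(seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
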