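import numpy as np
import pytest

from purehap import validate_genotype_matrix
from purehap.simulate import generate_genotypes, generate_haplotype_pool, generate_mask

#: Worked five-genotype, four-SNP example instance used across the suite;
#: its pure parsimony optimum is 4 distinct haplotypes.
WORKED_EXAMPLE_ROWS = [
    [2, 1, 1, 2],
    [1, 0, 1, 1],
    [1, 0, 2, 2],
    [2, 0, 1, 1],
    [2, 1, 0, 1],
]


@pytest.fixture
def worked_example():
    return validate_genotype_matrix(WORKED_EXAMPLE_ROWS)


def make_random_instance(seed: int, n_range=(2, 5), m_range=(3, 6), pool_range=(2, 4),
                         error_ratio: float = 0.0):
    """One seeded random instance: genotypes from a pooled pairing plus an
    exact-count mask.  Deterministic per seed; retries pool/pairing seeds
    until the pairing succeeds (tiny pools cannot always fill n rows)."""
    rng = np.random.default_rng(seed)
    while True:
        n = int(rng.integers(n_range[0], n_range[1] + 1))
        m = int(rng.integers(m_range[0], m_range[1] + 1))
        pool_size = int(rng.integers(pool_range[0], pool_range[1] + 1))
        pool = generate_haplotype_pool(pool_size, m, int(rng.integers(0, 2**31)))
        try:
            G = generate_genotypes(pool, n, seed=int(rng.integers(0, 2**31)),
                                   max_retries_per_row=50)
        except Exception:
            continue
        M = generate_mask(G.n, G.m, error_ratio, int(rng.integers(0, 2**31)))
        return G, M
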