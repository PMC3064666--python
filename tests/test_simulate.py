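"""Synthetic-instance generator contracts: pools, pairings, masks."""

import numpy as np
import pytest

from purehap.datamodel import validate_genotype_matrix
from purehap.simulate import (
    SimulationConfig,
    SimulationError,
    generate_genotypes,
    generate_haplotype_pool,
    generate_instance,
    generate_mask,
    inject_errors,
)


class TestHaplotypePool:
    def test_shape_and_distinctness(self):
        pool = generate_haplotype_pool(4, 10, seed=42)
        assert len(pool) == 4
        assert len(set(pool)) == 4
        assert all(len(h) == 10 and set(h) <= {0, 1} for h in pool)

    def test_deterministic_per_seed(self):
        assert generate_haplotype_pool(5, 8, seed=7) == generate_haplotype_pool(5, 8, seed=7)

    def test_pool_larger_than_space_rejected(self):
        with pytest.raises(SimulationError):
            generate_haplotype_pool(9, 3, seed=0)

    def test_full_space_pool(self):
        pool = generate_haplotype_pool(8, 3, seed=0)
        assert sorted(pool) == sorted({h for h in pool})
        assert len(pool) == 8


class TestGenotypePairing:
    def test_rows_are_pool_pair_sums(self):
        pool = generate_haplotype_pool(10, 6, seed=3)
        G = generate_genotypes(pool, 20, seed=5)
        assert G.n == 20
        sums = {
            tuple(a + b for a, b in zip(ha, hb)) for ha in pool for hb in pool
        }
        for row in G.entries:
            assert tuple(int(v) for v in row) in sums

    def test_generated_matrix_validates(self):
        pool = generate_haplotype_pool(6, 8, seed=11)
        G = generate_genotypes(pool, 15, seed=13)
        again = validate_genotype_matrix(G.entries)
        assert again.n == 15  # distinct and non-degenerate already

    def test_forced_single_outcome(self):
        G = generate_genotypes([(0, 1), (1, 0)], 1, seed=0)
        assert G.entries.tolist() == [[1, 1]]

    def test_impossible_request_raises(self):
        with pytest.raises(SimulationError, match="retry budget"):
            generate_genotypes([(0, 1), (1, 0)], 2, seed=0, max_retries_per_row=10)

    def test_nonuniform_skew_concentrates_parents(self):
        pool = generate_haplotype_pool(8, 10, seed=2)
        G = generate_genotypes(pool, 8, mode="nonuniform", concentration=0.1, seed=9)
        # with strong skew one pool haplotype dominates the pairings
        counts = []
        for h in pool:
            c = sum(
                1
                for row in G.entries
                if all(v - a in (0, 1) for v, a in zip(row, h))
            )
            counts.append(c)
        assert max(counts) >= G.n // 2

    def test_deterministic_per_seed(self):
        pool = generate_haplotype_pool(5, 6, seed=1)
        a = generate_genotypes(pool, 10, seed=4)
        b = generate_genotypes(pool, 10, seed=4)
        assert a.entries.tolist() == b.entries.tolist()


class TestMask:
    @pytest.mark.parametrize(
        "n, m, ratio, expected_ones",
        [(50, 10, 0.01, 5), (30, 100, 0.15, 450), (10, 8, 0.0, 0), (7, 9, 0.5, 32)],
    )
    def test_exact_ones_count(self, n, m, ratio, expected_ones):
        mask = generate_mask(n, m, ratio, seed=0)
        assert mask.entries.shape == (n, m)
        assert int(mask.entries.sum()) == expected_ones

    def test_deterministic_per_seed(self):
        a = generate_mask(20, 10, 0.1, seed=3)
        b = generate_mask(20, 10, 0.1, seed=3)
        assert a.entries.tolist() == b.entries.tolist()

    def test_ratio_out_of_range(self):
        with pytest.raises(SimulationError):
            generate_mask(5, 5, 1.5, seed=0)


class TestInjectErrors:
    def test_zero_mask_is_identity(self):
        g = np.array([[1, 2], [0, 1]])
        out = inject_errors(g, np.zeros_like(g), seed=0)
        assert out.tolist() == g.tolist()

    def test_masked_entries_change_value(self):
        g = np.array([[0, 1, 2]])
        mask = np.array([[1, 1, 1]])
        for seed in range(5):
            out = inject_errors(g, mask, seed=seed)
            assert all(out[0, j] != g[0, j] for j in range(3))
            assert set(np.unique(out)) <= {0, 1, 2}

    def test_deterministic_per_seed(self):
        g = np.array([[0, 1, 2], [2, 1, 0]])
        mask = np.array([[1, 0, 1], [0, 1, 1]])
        assert inject_errors(g, mask, 5).tolist() == inject_errors(g, mask, 5).tolist()


class TestConfig:
    def test_instance_generation_is_reproducible(self):
        cfg = SimulationConfig(pool_size=7, m=8, n=12, error_ratio=0.1, seed=21)
        g1, m1, p1 = generate_instance(cfg)
        g2, m2, p2 = generate_instance(cfg)
        assert g1.entries.tolist() == g2.entries.tolist()
        assert m1.entries.tolist() == m2.entries.tolist()
        assert p1 == p2

    def test_invalid_config_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(pool_size=1)
        with pytest.raises(SimulationError):
            SimulationConfig(pool_size=100, m=3)
        with pytest.raises(SimulationError):
            SimulationConfig(error_ratio=1.2)
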