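"""Domain types: validation, resolution semantics, correction rules."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from purehap.datamodel import (
    Correction,
    DegenerateGenotypeError,
    InvalidCorrectionError,
    InvalidGenotypeError,
    allowed_corrections,
    apply_corrections,
    doubled_resolution,
    enumerate_resolving_pairs,
    is_resolved,
    validate_error_mask,
    validate_genotype_matrix,
)


class TestValidateGenotypeMatrix:
    def test_worked_example_dimensions(self, worked_example):
        assert worked_example.n == 5
        assert worked_example.m == 4
        assert worked_example.entries[0].tolist() == [2, 1, 1, 2]

    def test_alphabet_violation(self):
        with pytest.raises(InvalidGenotypeError):
            validate_genotype_matrix([[0, 1, 3]])

    def test_degenerate_row_rejected(self):
        with pytest.raises(DegenerateGenotypeError, match="degenerate"):
            validate_genotype_matrix([[0, 2, 0]])

    def test_empty_matrix_rejected(self):
        with pytest.raises(InvalidGenotypeError):
            validate_genotype_matrix(np.empty((0, 0)))

    def test_duplicates_removed_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            gm = validate_genotype_matrix([[1, 2], [1, 0], [1, 2]])
        assert gm.n == 2
        assert gm.kept_rows == (0, 1)

    def test_mask_aligned_to_kept_rows(self):
        with pytest.warns(UserWarning):
            gm = validate_genotype_matrix([[1, 2], [1, 0], [1, 2]])
        mask = validate_error_mask([[1, 0], [0, 1], [1, 1]], gm)
        assert mask.entries.tolist() == [[1, 0], [0, 1]]

    def test_mask_shape_mismatch(self, worked_example):
        with pytest.raises(InvalidGenotypeError):
            validate_error_mask(np.zeros((5, 3), dtype=int), worked_example)


class TestResolution:
    @pytest.mark.parametrize(
        "g, ha, hb, expected",
        [
            ((1, 0, 2, 2), (1, 0, 1, 1), (0, 0, 1, 1), True),
            ((2, 1, 1, 2), (1, 0, 1, 1), (1, 0, 1, 1), False),
            ((1, 1), (0, 1), (1, 0), True),
        ],
    )
    def test_is_resolved(self, g, ha, hb, expected):
        assert is_resolved(g, ha, hb) is expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            is_resolved((1, 1), (0, 1, 0), (1, 0))

    def test_single_heterozygous_site_has_one_pair(self):
        pairs = enumerate_resolving_pairs((0, 2, 1))
        assert pairs == {((0, 1, 0), (0, 1, 1))}

    def test_pair_count_is_two_to_k_minus_one(self):
        assert len(enumerate_resolving_pairs((1, 0, 1, 1))) == 4

    def test_degenerate_has_no_pairs(self):
        with pytest.raises(DegenerateGenotypeError):
            enumerate_resolving_pairs((0, 2, 0))

    @pytest.mark.parametrize("m", [3, 4])
    def test_matches_exhaustive_pair_enumeration(self, m):
        """Enumerated pairs equal brute force over all 2^m x 2^m haplotype
        pairs, and their count is 2^(k-1)."""
        haplotypes = list(product((0, 1), repeat=m))
        for g in product((0, 1, 2), repeat=m):
            if 1 not in g:
                continue
            brute = {
                tuple(sorted((ha, hb)))
                for ha in haplotypes
                for hb in haplotypes
                if all(x + y == v for x, y, v in zip(ha, hb, g))
            }
            fast = enumerate_resolving_pairs(g)
            assert fast == brute
            k = sum(1 for v in g if v == 1)
            assert len(fast) == 2 ** (k - 1)
            assert all(is_resolved(g, ha, hb) for ha, hb in fast)

    @settings(derandomize=True, max_examples=60)
    @given(
        g=st.lists(st.sampled_from([0, 1, 2]), min_size=1, max_size=6).filter(
            lambda row: 1 in row
        )
    )
    def test_pair_enumeration_properties(self, g):
        """Every returned pair resolves g and the count is 2^(k-1)."""
        pairs = enumerate_resolving_pairs(g)
        k = sum(1 for v in g if v == 1)
        assert len(pairs) == 2 ** (k - 1)
        for ha, hb in pairs:
            assert is_resolved(g, ha, hb)
            assert tuple(sorted((ha, hb))) == (ha, hb)

    def test_doubled_resolution_of_degenerate_row(self):
        assert doubled_resolution((0, 2, 2)) == (0, 1, 1)
        with pytest.raises(ValueError):
            doubled_resolution((0, 1, 2))


class TestCorrections:
    @pytest.mark.parametrize(
        "entry, deltas",
        [(0, {+1, +2}), (2, {-1, -2}), (1, {+1, -1})],
    )
    def test_allowed_deltas(self, entry, deltas):
        assert allowed_corrections(entry) == deltas

    def test_zero_delta_never_listed_and_values_stay_in_alphabet(self):
        for entry in (0, 1, 2):
            deltas = allowed_corrections(entry)
            assert 0 not in deltas
            assert all(entry + d in (0, 1, 2) for d in deltas)

    def test_entry_outside_alphabet(self):
        with pytest.raises(InvalidGenotypeError):
            allowed_corrections(3)

    def test_apply_single_correction(self):
        corrected = apply_corrections(
            np.array([[1, 2]]),
            np.array([[0, 1]]),
            [Correction(1, 2, -2, 0)],
        )
        assert corrected.tolist() == [[1, 0]]

    def test_correction_at_unmasked_cell(self):
        with pytest.raises(InvalidCorrectionError, match="unmasked"):
            apply_corrections(
                np.array([[1, 2]]), np.array([[1, 0]]), [Correction(1, 2, -2, 0)]
            )

    def test_two_corrections_one_cell(self):
        with pytest.raises(InvalidCorrectionError, match="two corrections"):
            apply_corrections(
                np.array([[1, 2]]),
                np.array([[0, 1]]),
                [Correction(1, 2, -1, 1), Correction(1, 2, -2, 0)],
            )

    def test_disallowed_delta(self):
        with pytest.raises(InvalidCorrectionError, match="not allowed"):
            apply_corrections(
                np.array([[0, 1]]), np.array([[1, 0]]), [Correction(1, 1, -1, -1)]
            )

    def test_empty_corrections_is_identity(self):
        g = np.array([[1, 2], [1, 0]])
        out = apply_corrections(g, np.ones_like(g), [])
        assert out.tolist() == g.tolist()
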