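"""Frequency and contingency tables: golden example, oracles, marginal reduction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwasbits.bitops import BitVector, count_weight_evaluations
from gwasbits.codec import codes_to_symbols, encode_2bit, encode_3bit
from gwasbits.tables import (
    PhenotypeSplit,
    contingency_full,
    contingency_marginal,
    frequency_table,
    frequency_table_2bit,
    frequency_table_3bit,
)

from conftest import (
    M_A_FREQ,
    M_B_FREQ,
    PAIR_CELLS,
    oracle_contingency,
    oracle_frequency,
    random_genotypes,
)


class TestFrequencyTable:
    def test_worked_example_two_bit(self, marker_a_genotypes, marker_b_genotypes):
        assert frequency_table_2bit(encode_2bit(marker_a_genotypes)).as_tuple() == M_A_FREQ
        assert frequency_table_2bit(encode_2bit(marker_b_genotypes)).as_tuple() == M_B_FREQ

    def test_worked_example_three_bit(self, marker_a_genotypes):
        assert frequency_table_3bit(encode_3bit(marker_a_genotypes)).as_tuple() == M_A_FREQ

    def test_two_bit_path_uses_three_weight_evaluations(self, marker_a_genotypes):
        with count_weight_evaluations() as c:
            frequency_table_2bit(encode_2bit(marker_a_genotypes))
        assert c.count == 3

    def test_empty_subset_mask(self, marker_a_genotypes):
        mask = BitVector.zeros(5)
        t = frequency_table_2bit(encode_2bit(marker_a_genotypes), mask)
        assert t.as_tuple() == (0, 0, 0, 0) and t.n == 0

    def test_all_missing_marker_three_bit(self):
        t = frequency_table_3bit(encode_3bit(["NN"] * 9))
        assert t.as_tuple() == (0, 0, 0, 9)

    def test_mask_length_mismatch(self, marker_a_genotypes):
        with pytest.raises(ValueError, match="mask length"):
            frequency_table_2bit(encode_2bit(marker_a_genotypes), BitVector.zeros(6))

    @pytest.mark.parametrize("encoder,table_fn", [
        (encode_2bit, frequency_table_2bit),
        (encode_3bit, frequency_table_3bit),
    ])
    def test_random_marker_matches_loop_oracle(self, rng, encoder, table_fn):
        codes = random_genotypes(rng, 1000)
        mask = rng.random(1000) < 0.6
        expected = oracle_frequency(codes, mask)
        got = table_fn(encoder(codes), BitVector.from_bools(mask))
        assert got.as_tuple() == expected


class TestContingencyFull:
    def test_worked_example_reproduces_all_cells_and_marginals(
        self, marker_a_genotypes, marker_b_genotypes
    ):
        t = contingency_full(encode_2bit(marker_a_genotypes), encode_2bit(marker_b_genotypes))
        assert np.array_equal(t.cells, PAIR_CELLS)
        assert tuple(t.row_marginals) == M_A_FREQ
        assert tuple(t.col_marginals) == M_B_FREQ

    def test_self_pair_is_diagonal_frequency_table(self, rng):
        codes = random_genotypes(rng, 120)
        m = encode_2bit(codes)
        t = contingency_full(m, m)
        freq = frequency_table_2bit(m)
        # diagonal over non-missing classes; off-diagonal non-missing cells 0
        assert tuple(np.diag(t.cells)[:3]) == freq.as_tuple()[:3]
        off = t.cells[:3, :3] - np.diag(np.diag(t.cells[:3, :3]))
        assert not off.any()

    def test_random_pair_matches_double_loop_oracle(self, rng):
        a = random_genotypes(rng, 2000)
        b = random_genotypes(rng, 2000)
        t = contingency_full(encode_2bit(a), encode_2bit(b))
        assert np.array_equal(t.cells, oracle_contingency(a, b))

    def test_cross_encoding_equivalence(self, rng):
        for _ in range(20):
            a = random_genotypes(rng, 257)
            b = random_genotypes(rng, 257)
            t2 = contingency_full(encode_2bit(a), encode_2bit(b))
            t3 = contingency_full(encode_3bit(a), encode_3bit(b))
            assert np.array_equal(t2.cells, t3.cells)

    def test_encoding_tag_mismatch_rejected(self, rng):
        codes = random_genotypes(rng, 30)
        with pytest.raises(ValueError, match="encoding mismatch"):
            contingency_full(encode_2bit(codes), encode_3bit(codes))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=2, max_value=200), st.randoms(use_true_random=False))
    def test_oracle_equivalence_with_random_masks(self, n, pyrandom):
        a = np.array([pyrandom.randrange(4) for _ in range(n)], dtype=np.int8)
        b = np.array([pyrandom.randrange(4) for _ in range(n)], dtype=np.int8)
        mask = np.array([pyrandom.random() < 0.7 for _ in range(n)])
        t = contingency_full(encode_2bit(a), encode_2bit(b), BitVector.from_bools(mask))
        assert np.array_equal(t.cells, oracle_contingency(a, b, mask))
        assert int(t.cells.sum()) == int(mask.sum())

    def test_subset_additivity_case_plus_control(self, rng):
        a = random_genotypes(rng, 333)
        b = random_genotypes(rng, 333)
        split = PhenotypeSplit.from_labels(rng.random(333) < 0.4)
        ma, mb = encode_2bit(a), encode_2bit(b)
        whole = contingency_full(ma, mb)
        case = contingency_full(ma, mb, split.case_mask)
        ctrl = contingency_full(ma, mb, split.control_mask)
        assert np.array_equal(case.cells + ctrl.cells, whole.cells)


class TestContingencyMarginal:
    @staticmethod
    def _missing_free_pair(rng, n=1000):
        a = rng.integers(1, 4, size=n).astype(np.int8)
        b = rng.integers(1, 4, size=n).astype(np.int8)
        return encode_2bit(a), encode_2bit(b)

    def test_equals_full_table_on_missing_free_input(self, rng):
        ma, mb = self._missing_free_pair(rng)
        fa, fb = frequency_table_2bit(ma), frequency_table_2bit(mb)
        res = contingency_marginal(ma, mb, fa, fb)
        assert not res.used_fallback
        assert np.array_equal(res.table.cells, contingency_full(ma, mb).cells)

    def test_exactly_four_direct_weight_evaluations(self, rng):
        ma, mb = self._missing_free_pair(rng)
        fa, fb = frequency_table_2bit(ma), frequency_table_2bit(mb)
        with count_weight_evaluations() as c:
            res = contingency_marginal(ma, mb, fa, fb)
        assert not res.used_fallback
        assert c.count == 4

    def test_falls_back_when_missing_present(self, marker_a_genotypes, marker_b_genotypes):
        ma, mb = encode_2bit(marker_a_genotypes), encode_2bit(marker_b_genotypes)
        fa, fb = frequency_table_2bit(ma), frequency_table_2bit(mb)
        res = contingency_marginal(ma, mb, fa, fb)
        assert res.used_fallback  # M_A has a missing genotype
        assert np.array_equal(res.table.cells, PAIR_CELLS)

    def test_degenerate_all_homozygous_marker(self, rng):
        n = 200
        a = np.full(n, 1, dtype=np.int8)  # all AA
        b = rng.integers(1, 4, size=n).astype(np.int8)
        ma, mb = encode_2bit(a), encode_2bit(b)
        fa, fb = frequency_table_2bit(ma), frequency_table_2bit(mb)
        res = contingency_marginal(ma, mb, fa, fb)
        assert tuple(res.table.cells[0, :3]) == fb.as_tuple()[:3]
        assert not res.table.cells[1:].any()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=2, max_value=150), st.randoms(use_true_random=False))
    def test_marginal_equivalent_to_full_whenever_missing_free(self, n, pyrandom):
        a = np.array([pyrandom.randrange(1, 4) for _ in range(n)], dtype=np.int8)
        b = np.array([pyrandom.randrange(1, 4) for _ in range(n)], dtype=np.int8)
        ma, mb = encode_2bit(a), encode_2bit(b)
        fa, fb = frequency_table_2bit(ma), frequency_table_2bit(mb)
        res = contingency_marginal(ma, mb, fa, fb)
        assert not res.used_fallback
        assert np.array_equal(res.table.cells, contingency_full(ma, mb).cells)


class TestPhenotypeSplit:
    def test_overlapping_masks_rejected(self):
        ones = BitVector.ones(10)
        with pytest.raises(ValueError, match="overlap"):
            PhenotypeSplit(ones, ones)

    def test_from_labels_partitions_cohort(self, rng):
        is_case = rng.random(97) < 0.5
        split = PhenotypeSplit.from_labels(is_case)
        assert split.n_cases() + split.n_controls() == 97


def test_contingency_table_tsv_mirrors_pair_layout(
    marker_a_genotypes, marker_b_genotypes
):
    t = contingency_full(encode_2bit(marker_a_genotypes), encode_2bit(marker_b_genotypes))
    text = t.to_tsv()
    lines = text.splitlines()
    assert lines[0].split("\t")[1:5] == ["AA", "Aa", "aa", "NN"]
    assert lines[1].split("\t") == ["AA", "1", "0", "1", "0", "2"]
    assert lines[-1].split("\t") == ["C_B", "2", "1", "2", "0", "5"]
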