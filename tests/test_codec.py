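"""Genotype encodings: bit patterns, round trips, layout conversions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwasbits.bitops import BitVector
from gwasbits.codec import (
    GenotypeMatrix,
    GenotypeTokenError,
    as_codes,
    codes_to_symbols,
    convert_layout,
    decode,
    decode_codes,
    encode_2bit,
    encode_3bit,
    encode_paired,
    expand_2to3_block,
)
from gwasbits.simulate import simulate_matrix

from conftest import random_genotypes


def bits(v: BitVector):
    return list(v.to_bools().astype(int))


class TestTwoBitEncoding:
    def test_worked_example_marker_a(self, marker_a_genotypes):
        m = encode_2bit(marker_a_genotypes)
        assert bits(m.v1) == [1, 0, 1, 1, 0]  # AA or aa indicator
        assert bits(m.v2) == [0, 1, 0, 1, 0]  # Aa or aa indicator

    def test_worked_example_marker_b(self, marker_b_genotypes):
        m = encode_2bit(marker_b_genotypes)
        assert bits(m.v1) == [1, 1, 1, 1, 0]
        assert bits(m.v2) == [0, 0, 1, 1, 1]

    def test_all_missing_is_all_zero(self):
        m = encode_2bit(["NN"] * 7)
        assert bits(m.v1) == [0] * 7 and bits(m.v2) == [0] * 7
        assert all(decode(m, i) == "NN" for i in range(7))

    def test_bad_token_reports_position(self):
        with pytest.raises(GenotypeTokenError, match="position 2"):
            encode_2bit(["AA", "Aa", "XX"])


class TestThreeBitEncoding:
    def test_worked_example_marker_a(self, marker_a_genotypes):
        m = encode_3bit(marker_a_genotypes)
        assert bits(m.s_AA) == [1, 0, 1, 0, 0]
        assert bits(m.s_Aa) == [0, 1, 0, 0, 0]
        assert bits(m.s_aa) == [0, 0, 0, 1, 0]

    def test_worked_example_marker_b(self, marker_b_genotypes):
        m = encode_3bit(marker_b_genotypes)
        assert bits(m.s_AA) == [1, 1, 0, 0, 0]
        assert bits(m.s_Aa) == [0, 0, 0, 0, 1]
        assert bits(m.s_aa) == [0, 0, 1, 1, 0]

    def test_streams_mutually_exclusive_on_random_input(self, rng):
        codes = random_genotypes(rng, 500)
        m = encode_3bit(codes)
        for u, v in [(m.s_AA, m.s_Aa), (m.s_AA, m.s_aa), (m.s_Aa, m.s_aa)]:
            assert not np.any(u.blocks & v.blocks)


class TestDecode:
    def test_worked_example_individual_4_is_homozygous_minor(self, marker_a_genotypes):
        assert decode(encode_2bit(marker_a_genotypes), 3) == "aa"

    @pytest.mark.parametrize("encoder", [encode_2bit, encode_3bit, encode_paired])
    def test_round_trip_random_sequence(self, rng, encoder):
        codes = random_genotypes(rng, 200)
        m = encoder(codes)
        symbols = codes_to_symbols(codes)
        assert [decode(m, i) for i in range(200)] == symbols

    def test_index_out_of_range(self, marker_a_genotypes):
        with pytest.raises(IndexError):
            decode(encode_2bit(marker_a_genotypes), 5)

    # boundary lengths around the block width
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.sampled_from([1, 31, 32, 33, 63, 64, 65, 259]),
        st.sampled_from(["two_bit", "three_bit", "paired"]),
        st.sampled_from([32, 64]),
        st.randoms(use_true_random=False),
    )
    def test_round_trip_boundary_lengths(self, n, tag, width, pyrandom):
        codes = np.array([pyrandom.randrange(4) for _ in range(n)], dtype=np.int8)
        mat = GenotypeMatrix.from_codes([codes], encoding=tag, width=width)
        assert np.array_equal(mat.to_codes()[0], codes)


class TestExpandTwoToThree:
    def test_all_homozygous_minor_block(self):
        ones = (1 << 64) - 1
        b_aa_hom_major, b_het, b_hom_minor = expand_2to3_block(ones, ones)
        assert b_hom_minor == ones and b_aa_hom_major == 0 and b_het == 0

    def test_worked_example_block_matches_three_bit_table(self):
        # v1=10110, v2=01010 (LSB-first ints) -> AA=10100, Aa=01000, aa=00010
        v1 = 0b01101  # bit i = individual i
        v2 = 0b01010
        b_AA, b_Aa, b_aa = expand_2to3_block(v1, v2)
        assert b_AA == 0b00101
        assert b_Aa == 0b00010
        assert b_aa == 0b01000

    def test_expansion_equals_codec_composition(self, rng):
        codes = random_genotypes(rng, 300)
        m2 = encode_2bit(codes)
        m3 = encode_3bit(codes)
        b_AA, b_Aa, b_aa = expand_2to3_block(m2.v1.blocks, m2.v2.blocks)
        assert np.array_equal(b_AA, m3.s_AA.blocks)
        assert np.array_equal(b_Aa, m3.s_Aa.blocks)
        assert np.array_equal(b_aa, m3.s_aa.blocks)

    def test_two_and_three_bit_layouts_are_bit_consistent(self, rng):
        # v1 = sAA OR saa and v2 = sAa OR saa, blockwise
        codes = random_genotypes(rng, 450)
        m2, m3 = encode_2bit(codes), encode_3bit(codes)
        assert np.array_equal(m2.v1.blocks, m3.s_AA.blocks | m3.s_aa.blocks)
        assert np.array_equal(m2.v2.blocks, m3.s_Aa.blocks | m3.s_aa.blocks)


class TestConvertLayout:
    def test_two_three_two_round_trip_is_identity(self):
        mat, _, _ = simulate_matrix(100, 50, seed=7, encoding="two_bit")
        back = convert_layout(convert_layout(mat, "three_bit"), "two_bit")
        assert np.array_equal(back.to_codes(), mat.to_codes())
        for m1, m2 in zip(mat.markers, back.markers):
            assert m1.v1.equals(m2.v1) and m1.v2.equals(m2.v2)

    def test_paired_encoding_of_known_sequence(self):
        mat = GenotypeMatrix.from_codes([["AA", "Aa", "aa", "NN"]], encoding="paired")
        vec = convert_layout(mat, "two_bit")
        assert bits(vec.markers[0].v1) == [1, 0, 1, 0]
        assert bits(vec.markers[0].v2) == [0, 1, 1, 0]

    def test_identity_conversion_returns_equal_matrix(self):
        mat, _, _ = simulate_matrix(5, 20, seed=1)
        assert convert_layout(mat, "two_bit") is mat

    def test_unknown_tag_rejected(self):
        mat, _, _ = simulate_matrix(2, 8, seed=0)
        with pytest.raises(ValueError, match="unknown encoding"):
            convert_layout(mat, "four_bit")

    def test_all_three_layouts_agree_on_genotypes(self, rng):
        codes = np.vstack([random_genotypes(rng, 37) for _ in range(6)])
        base = GenotypeMatrix.from_codes(codes, encoding="two_bit")
        for tag in ("three_bit", "paired"):
            assert np.array_equal(convert_layout(base, tag).to_codes(), codes)


def test_storage_accounting_two_thirds():
    # per marker: 2n vs 3n bits before block rounding
    from gwasbits.simulate import size_calculator

    two = size_calculator(100, 64 * 5, "two_bit")
    three = size_calculator(100, 64 * 5, "three_bit")
    assert two * 3 == three * 2


def test_dosage_dialect_tokens():
    assert list(as_codes(["0", "1", "2", ".", "-9"])) == [1, 2, 3, 0, 0]
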