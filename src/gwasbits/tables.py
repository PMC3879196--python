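"""Frequency and pairwise contingency tables from encoded genotypes.

The per-marker frequency table (counts of AA/Aa/aa/NN over a sample subset)
and the pairwise 4x4 contingency table are the two counting workloads at the
heart of case/control association and epistasis scans.  Both reduce to
Hamming weights of Boolean combinations of indicator vectors:

* 2-bit frequency table: three weights — w1 = |v1|, w2 = |v2|,
  w3 = |v1 AND v2| — give n_aa = w3, n_AA = w1 - w3, n_Aa = w2 - w3 and the
  missing count by subtraction from the subset size.
* contingency table: each non-missing cell is the popcount of the AND of the
  two markers' genotype streams (for 2-bit input the streams are derived by
  the inline mask transform); the NN row/column is completed by subtraction
  from the per-marker marginals.
* marginal reduction: when neither marker has missing genotypes in the
  subset, only the four cells (AA,AA), (AA,Aa), (Aa,AA), (Aa,Aa) need direct
  popcounts; the other five non-missing cells follow from row/column sums.

Subset (case/control) restriction is an AND with a membership mask — the
matrix is stored once and never duplicated per phenotype group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .bitops import BitVector, combined_weight, hamming_weight
from .codec import (
    Marker,
    Marker2Bit,
    Marker3Bit,
    MarkerPaired,
    decode_codes,
    encode_2bit,
    expand_2to3,
)

__all__ = [
    "FrequencyTable",
    "ContingencyTable",
    "PhenotypeSplit",
    "frequency_table",
    "frequency_table_2bit",
    "frequency_table_3bit",
    "contingency_full",
    "contingency_marginal",
    "MarginalResult",
]

GENOTYPE_ORDER = ("AA", "Aa", "aa", "NN")


@dataclass(frozen=True)
class FrequencyTable:
    """Genotype class counts for one marker over a counted subset of size n."""

    n_AA: int
    n_Aa: int
    n_aa: int
    n_NN: int
    n: int

    def __post_init__(self) -> None:
        if self.n_AA + self.n_Aa + self.n_aa + self.n_NN != self.n:
            raise ValueError("frequency table counts must sum to the subset size")
        if min(self.n_AA, self.n_Aa, self.n_aa, self.n_NN) < 0:
            raise ValueError("negative genotype count")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n_AA, self.n_Aa, self.n_aa, self.n_NN)

    def to_tsv_row(self, label: str = "") -> str:
        return "\t".join([label, *map(str, self.as_tuple())])


@dataclass(frozen=True)
class ContingencyTable:
    """4x4 joint genotype counts for a marker pair, rows = marker A.

    ``cells[i, j]`` counts individuals with genotype ``GENOTYPE_ORDER[i]`` at
    marker A and ``GENOTYPE_ORDER[j]`` at marker B; row sums reproduce marker
    A's frequency table and column sums marker B's.
    """

    cells: np.ndarray
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", np.asarray(self.cells, dtype=np.int64))
        if self.cells.shape != (4, 4):
            raise ValueError("contingency table must be 4x4")
        if self.cells.min() < 0:
            raise ValueError("negative contingency cell")
        if int(self.cells.sum()) != self.n:
            raise ValueError("contingency cells must sum to the subset size")

    @property
    def row_marginals(self) -> np.ndarray:
        return self.cells.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.cells.sum(axis=0)

    def marginal_a(self) -> FrequencyTable:
        r = self.row_marginals
        return FrequencyTable(int(r[0]), int(r[1]), int(r[2]), int(r[3]), self.n)

    def marginal_b(self) -> FrequencyTable:
        c = self.col_marginals
        return FrequencyTable(int(c[0]), int(c[1]), int(c[2]), int(c[3]), self.n)

    def nonmissing(self) -> np.ndarray:
        """The 3x3 block over {AA, Aa, aa} x {AA, Aa, aa}."""
        return self.cells[:3, :3]

    def to_tsv(self) -> str:
        lines = ["\t".join(["", *GENOTYPE_ORDER, "C_A"])]
        for i, g in enumerate(GENOTYPE_ORDER):
            lines.append(
                "\t".join([g, *map(str, self.cells[i]), str(self.row_marginals[i])])
            )
        lines.append("\t".join(["C_B", *map(str, self.col_marginals), str(self.n)]))
        return "\n".join(lines)


@dataclass
class PhenotypeSplit:
    """Disjoint case/control membership masks covering the assigned cohort.

    Individuals with unknown phenotype may be absent from both masks; every
    individual present is in exactly one.
    """

    case_mask: BitVector
    control_mask: BitVector

    def __post_init__(self) -> None:
        if self.case_mask.length != self.control_mask.length:
            raise ValueError("case and control masks must span the same individuals")
        if int(np.bitwise_and(self.case_mask.blocks, self.control_mask.blocks).any()):
            raise ValueError("case and control masks overlap")

    @property
    def n(self) -> int:
        return self.case_mask.length

    @classmethod
    def from_labels(cls, is_case, width: int = 64, assigned=None) -> "PhenotypeSplit":
        """Build from a boolean case indicator; ``assigned`` masks out unknowns."""
        is_case = np.asarray(is_case, dtype=bool)
        if assigned is None:
            assigned = np.ones_like(is_case)
        assigned = np.asarray(assigned, dtype=bool)
        return cls(
            BitVector.from_bools(is_case & assigned, width=width),
            BitVector.from_bools(~is_case & assigned, width=width),
        )

    def n_cases(self) -> int:
        return hamming_weight(self.case_mask)

    def n_controls(self) -> int:
        return hamming_weight(self.control_mask)


# ---------------------------------------------------------------------------
# frequency tables
# ---------------------------------------------------------------------------


def _check_mask(n: int, subset_mask: Optional[BitVector]) -> None:
    if subset_mask is not None and subset_mask.length != n:
        raise ValueError(
            f"subset mask length {subset_mask.length} does not match n={n}"
        )


def frequency_table_2bit(
    m: Marker2Bit, subset_mask: Optional[BitVector] = None
) -> FrequencyTable:
    """Frequency table from the 2-bit layout with exactly three weight evaluations."""
    _check_mask(m.n, subset_mask)
    if subset_mask is None:
        u1, u2 = m.v1, m.v2
        size = m.n
    else:
        u1 = m.v1 & subset_mask
        u2 = m.v2 & subset_mask
        size = int(np.bitwise_count(subset_mask.blocks).sum())
    w1 = hamming_weight(u1)
    w2 = hamming_weight(u2)
    w3 = combined_weight(u1, u2, "and")
    return FrequencyTable(
        n_AA=w1 - w3, n_Aa=w2 - w3, n_aa=w3, n_NN=size - (w1 + w2 - w3), n=size
    )


def frequency_table_3bit(
    m: Marker3Bit, subset_mask: Optional[BitVector] = None
) -> FrequencyTable:
    """Frequency table from the 3-bit layout: one weight per stream."""
    _check_mask(m.n, subset_mask)
    if subset_mask is None:
        n_AA = hamming_weight(m.s_AA)
        n_Aa = hamming_weight(m.s_Aa)
        n_aa = hamming_weight(m.s_aa)
        size = m.n
    else:
        n_AA = combined_weight(m.s_AA, subset_mask, "and")
        n_Aa = combined_weight(m.s_Aa, subset_mask, "and")
        n_aa = combined_weight(m.s_aa, subset_mask, "and")
        size = int(np.bitwise_count(subset_mask.blocks).sum())
    return FrequencyTable(n_AA, n_Aa, n_aa, size - (n_AA + n_Aa + n_aa), size)


def frequency_table(
    m: Marker, subset_mask: Optional[BitVector] = None, width: int = 64
) -> FrequencyTable:
    """Dispatch on the marker's layout (paired markers go via the 2-bit path)."""
    if isinstance(m, Marker2Bit):
        return frequency_table_2bit(m, subset_mask)
    if isinstance(m, Marker3Bit):
        return frequency_table_3bit(m, subset_mask)
    if isinstance(m, MarkerPaired):
        return frequency_table_2bit(encode_2bit(decode_codes(m), width=width), subset_mask)
    raise TypeError(f"not a marker: {type(m).__name__}")


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------


def _streams(m: Marker, width: int) -> tuple[BitVector, BitVector, BitVector]:
    """Genotype indicator streams for any layout (2-bit via mask transform)."""
    if isinstance(m, Marker3Bit):
        return (m.s_AA, m.s_Aa, m.s_aa)
    if isinstance(m, Marker2Bit):
        e = expand_2to3(m)
        return (e.s_AA, e.s_Aa, e.s_aa)
    if isinstance(m, MarkerPaired):
        e = expand_2to3(encode_2bit(decode_codes(m), width=width))
        return (e.s_AA, e.s_Aa, e.s_aa)
    raise TypeError(f"not a marker: {type(m).__name__}")


def _masked(streams, subset_mask: Optional[BitVector]):
    if subset_mask is None:
        return streams
    return tuple(s & subset_mask for s in streams)


def _complete_with_marginals(
    inner: np.ndarray, freq_a: FrequencyTable, freq_b: FrequencyTable, size: int
) -> ContingencyTable:
    """Fill the NN row and column of a 4x4 table from the 3x3 block."""
    cells = np.zeros((4, 4), dtype=np.int64)
    cells[:3, :3] = inner
    fa = freq_a.as_tuple()  # (AA, Aa, aa, NN)
    fb = freq_b.as_tuple()
    for i in range(3):  # col NN: row total minus computed row sum
        cells[i, 3] = fa[i] - int(inner[i, :].sum())
    for j in range(3):  # row NN: column total minus computed column sum
        cells[3, j] = fb[j] - int(inner[:, j].sum())
    cells[3, 3] = size - int(cells.sum())
    return ContingencyTable(cells, size)


def contingency_full(
    a: Marker, b: Marker, subset_mask: Optional[BitVector] = None, width: int = 64
) -> ContingencyTable:
    """Full pairwise genotype count table: nine direct popcounts.

    Each non-missing cell is the Hamming weight of the AND of the two markers'
    genotype streams; the NN row/column is completed by subtraction from the
    two frequency tables.
    """
    if a.n != b.n:
        raise ValueError(f"marker lengths differ: {a.n} != {b.n}")
    if a.encoding != b.encoding:
        raise ValueError(f"encoding mismatch: {a.encoding} vs {b.encoding}")
    _check_mask(a.n, subset_mask)
    sa = _masked(_streams(a, width), subset_mask)
    sb = _masked(_streams(b, width), subset_mask)
    size = (
        a.n if subset_mask is None
        else int(np.bitwise_count(subset_mask.blocks).sum())
    )
    inner = np.empty((3, 3), dtype=np.int64)
    for i in range(3):
        for j in range(3):
            inner[i, j] = combined_weight(sa[i], sb[j], "and")
    # marginals from the streams themselves (no extra vector passes needed
    # beyond what the NN completion requires)
    fa = [int(np.bitwise_count(s.blocks).sum()) for s in sa]
    fb = [int(np.bitwise_count(s.blocks).sum()) for s in sb]
    freq_a = FrequencyTable(fa[0], fa[1], fa[2], size - sum(fa), size)
    freq_b = FrequencyTable(fb[0], fb[1], fb[2], size - sum(fb), size)
    return _complete_with_marginals(inner, freq_a, freq_b, size)


class MarginalResult(NamedTuple):
    """Contingency table plus which algorithm actually produced it."""

    table: ContingencyTable
    used_fallback: bool


def contingency_marginal(
    a: Marker,
    b: Marker,
    freq_a: FrequencyTable,
    freq_b: FrequencyTable,
    subset_mask: Optional[BitVector] = None,
    width: int = 64,
) -> MarginalResult:
    """Contingency table via the marginal reduction: four direct popcounts.

    Exact only when both markers are missing-free in the counted subset; with
    missing genotypes the four computed cells plus marginals underdetermine
    the 4x4 table, so this falls back to :func:`contingency_full` and flags
    it rather than return approximate counts.
    """
    if freq_a.n != freq_b.n:
        raise ValueError("frequency tables computed over different subsets")
    if freq_a.n_NN > 0 or freq_b.n_NN > 0:
        return MarginalResult(contingency_full(a, b, subset_mask, width), True)
    sa = _masked(_streams(a, width), subset_mask)
    sb = _masked(_streams(b, width), subset_mask)
    size = freq_a.n
    c = np.zeros((4, 4), dtype=np.int64)
    # the only four direct weight evaluations
    c[0, 0] = combined_weight(sa[0], sb[0], "and")
    c[0, 1] = combined_weight(sa[0], sb[1], "and")
    c[1, 0] = combined_weight(sa[1], sb[0], "and")
    c[1, 1] = combined_weight(sa[1], sb[1], "and")
    fa = freq_a.as_tuple()
    fb = freq_b.as_tuple()
    c[0, 2] = fa[0] - c[0, 0] - c[0, 1]
    c[1, 2] = fa[1] - c[1, 0] - c[1, 1]
    c[2, 0] = fb[0] - c[0, 0] - c[1, 0]
    c[2, 1] = fb[1] - c[0, 1] - c[1, 1]
    c[2, 2] = fa[2] - c[2, 0] - c[2, 1]
    return MarginalResult(ContingencyTable(c, size), False)
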