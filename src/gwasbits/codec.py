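"""Genotype encodings: 2-bit vectored, 3-bit vectored, and paired-bit layouts.

A biallelic unphased genotype is one of four symbols: ``AA`` (homozygous
major), ``Aa`` (heterozygous, phase collapsed), ``aa`` (homozygous minor) and
``NN`` (missing).  Four symbols need two bits, the information-theoretic
bound, and the 2-bit vectored layout reaches it:

==========  ===========  ===========
genotype    v1 (AA|aa)   v2 (Aa|aa)
==========  ===========  ===========
NN          0            0
AA          1            0
Aa          0            1
aa          1            1
==========  ===========  ===========

The 3-bit vectored layout keeps one indicator stream per non-missing genotype
(missing is the all-clear code); the paired layout stores the two bits of an
individual adjacently, four individuals per byte, as PLINK 1 BED files do.

Internally genotypes are small integer codes ``NN=0, AA=1, Aa=2, aa=3``; the
code's low bit is the v1 indicator and its high bit the v2 indicator, so the
2-bit encoding is a literal bit-slice of the code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np

from .bitops import ALLOWED_WIDTHS, BitVector

__all__ = [
    "NN", "AA", "Aa", "aa",
    "GENOTYPE_SYMBOLS",
    "as_codes", "codes_to_symbols",
    "Marker2Bit", "Marker3Bit", "MarkerPaired",
    "GenotypeMatrix",
    "encode_2bit", "encode_3bit", "encode_paired",
    "decode", "decode_codes",
    "expand_2to3_block", "expand_2to3",
    "convert_layout",
    "ENCODING_TAGS",
]

NN, AA, Aa, aa = 0, 1, 2, 3
GENOTYPE_SYMBOLS = ("NN", "AA", "Aa", "aa")  # indexed by code

ENCODING_TAGS = ("two_bit", "three_bit", "paired")

# token dialects accepted by the text format: symbolic and minor-allele dosage
_TOKEN_TO_CODE = {
    "NN": NN, "AA": AA, "Aa": Aa, "aA": Aa, "aa": aa,
    "0": AA, "1": Aa, "2": aa, ".": NN, "-9": NN,
}

# PLINK 1 BED bit-pair codes (A1 = minor allele "a"):
#   00 hom A1 (aa), 01 missing, 10 het, 11 hom A2 (AA)
_CODE_TO_PLINK = np.array([0b01, 0b11, 0b10, 0b00], dtype=np.uint8)
_PLINK_TO_CODE = np.array([aa, NN, Aa, AA], dtype=np.int8)
PLINK_MISSING_PAIR = 0b01


class GenotypeTokenError(ValueError):
    """Raised when a genotype token is outside the accepted dialects."""

    def __init__(self, token: object, position: int):
        self.token = token
        self.position = position
        super().__init__(f"unrecognized genotype token {token!r} at position {position}")


def as_codes(genotypes) -> np.ndarray:
    """Normalize a genotype sequence to an int8 code array (NN=0..aa=3).

    Accepts string tokens in the symbolic (``AA/Aa/aa/NN``) or dosage
    (``0/1/2``, ``.``/``-9`` missing) dialects, or integer codes directly.
    """
    if isinstance(genotypes, np.ndarray) and genotypes.dtype.kind in "iu":
        codes = genotypes.astype(np.int8, copy=False)
        if codes.size and (codes.min() < 0 or codes.max() > 3):
            bad = int(np.argmax((codes < 0) | (codes > 3)))
            raise GenotypeTokenError(int(codes[bad]), bad)
        return codes
    out = np.empty(len(genotypes), dtype=np.int8)
    for i, g in enumerate(genotypes):
        if isinstance(g, (int, np.integer)):
            if not 0 <= g <= 3:
                raise GenotypeTokenError(g, i)
            out[i] = g
            continue
        code = _TOKEN_TO_CODE.get(str(g))
        if code is None:
            raise GenotypeTokenError(g, i)
        out[i] = code
    return out


def codes_to_symbols(codes: np.ndarray) -> list[str]:
    return [GENOTYPE_SYMBOLS[c] for c in codes]


# ---------------------------------------------------------------------------
# marker containers
# ---------------------------------------------------------------------------


@dataclass
class Marker2Bit:
    """One marker's genotypes as two indicator vectors (v1 = AA|aa, v2 = Aa|aa)."""

    v1: BitVector
    v2: BitVector
    n: int

    def __post_init__(self) -> None:
        if not (self.v1.length == self.v2.length == self.n):
            raise ValueError("2-bit marker vectors must both span n individuals")

    @property
    def width(self) -> int:
        return self.v1.width

    encoding = "two_bit"


@dataclass
class Marker3Bit:
    """One marker's genotypes as three mutually exclusive indicator streams."""

    s_AA: BitVector
    s_Aa: BitVector
    s_aa: BitVector
    n: int

    def __post_init__(self) -> None:
        if not (self.s_AA.length == self.s_Aa.length == self.s_aa.length == self.n):
            raise ValueError("3-bit marker streams must all span n individuals")

    @property
    def width(self) -> int:
        return self.s_AA.width

    encoding = "three_bit"


@dataclass
class MarkerPaired:
    """One marker's genotypes as adjacent bit pairs, 4 individuals per byte."""

    data: np.ndarray  # uint8, length ceil(n/4)
    n: int

    def __post_init__(self) -> None:
        self.data = np.ascontiguousarray(self.data, dtype=np.uint8)
        if len(self.data) != -(-self.n // 4):
            raise ValueError("paired marker byte count inconsistent with n")

    encoding = "paired"


Marker = Union[Marker2Bit, Marker3Bit, MarkerPaired]


# ---------------------------------------------------------------------------
# encoders / decoders
# ---------------------------------------------------------------------------


def encode_2bit(genotypes, width: int = 64) -> Marker2Bit:
    codes = as_codes(genotypes)
    if codes.size == 0:
        raise ValueError("cannot encode an empty genotype sequence")
    v1 = BitVector.from_bools(codes & 1, width=width)
    v2 = BitVector.from_bools((codes >> 1) & 1, width=width)
    return Marker2Bit(v1, v2, len(codes))


def encode_3bit(genotypes, width: int = 64) -> Marker3Bit:
    codes = as_codes(genotypes)
    if codes.size == 0:
        raise ValueError("cannot encode an empty genotype sequence")
    return Marker3Bit(
        BitVector.from_bools(codes == AA, width=width),
        BitVector.from_bools(codes == Aa, width=width),
        BitVector.from_bools(codes == aa, width=width),
        len(codes),
    )


def encode_paired(genotypes) -> MarkerPaired:
    codes = as_codes(genotypes)
    if codes.size == 0:
        raise ValueError("cannot encode an empty genotype sequence")
    pairs = _CODE_TO_PLINK[codes]
    pad = (-len(pairs)) % 4
    if pad:
        # trailing unused bit-pairs carry the missing code
        pairs = np.concatenate([pairs, np.full(pad, PLINK_MISSING_PAIR, dtype=np.uint8)])
    quads = pairs.reshape(-1, 4)
    packed = quads[:, 0] | (quads[:, 1] << 2) | (quads[:, 2] << 4) | (quads[:, 3] << 6)
    return MarkerPaired(packed.astype(np.uint8), len(codes))


def decode_codes(marker: Marker) -> np.ndarray:
    """Decode a whole marker back to its int8 code array."""
    if isinstance(marker, Marker2Bit):
        b1 = marker.v1.to_bools().astype(np.int8)
        b2 = marker.v2.to_bools().astype(np.int8)
        return b1 | (b2 << 1)
    if isinstance(marker, Marker3Bit):
        codes = np.zeros(marker.n, dtype=np.int8)
        codes[marker.s_AA.to_bools()] = AA
        codes[marker.s_Aa.to_bools()] = Aa
        codes[marker.s_aa.to_bools()] = aa
        return codes
    if isinstance(marker, MarkerPaired):
        b = marker.data
        pairs = np.empty(len(b) * 4, dtype=np.uint8)
        for k in range(4):  # per-byte de-interleave masks
            pairs[k::4] = (b >> (2 * k)) & 0b11
        return _PLINK_TO_CODE[pairs[: marker.n]]
    raise TypeError(f"not a marker: {type(marker).__name__}")


def decode(marker: Marker, i: int) -> str:
    """Genotype symbol of individual ``i`` — inverse of the encoder."""
    if not (0 <= i < marker.n):
        raise IndexError(f"individual index {i} out of range for n={marker.n}")
    if isinstance(marker, Marker2Bit):
        return GENOTYPE_SYMBOLS[int(marker.v1.get(i)) | (int(marker.v2.get(i)) << 1)]
    if isinstance(marker, Marker3Bit):
        if marker.s_AA.get(i):
            return "AA"
        if marker.s_Aa.get(i):
            return "Aa"
        if marker.s_aa.get(i):
            return "aa"
        return "NN"
    if isinstance(marker, MarkerPaired):
        pair = (int(marker.data[i // 4]) >> (2 * (i % 4))) & 0b11
        return GENOTYPE_SYMBOLS[_PLINK_TO_CODE[pair]]
    raise TypeError(f"not a marker: {type(marker).__name__}")


def expand_2to3_block(b1: int, b2: int, width: int = 64):
    """Derive the three genotype indicator blocks from one 2-bit block pair.

    Returns ``(bAA, bAa, baa)`` where ``baa = b1 AND b2``,
    ``bAA = b1 AND NOT b2`` and ``bAa = b2 AND NOT b1``.  This is the inline
    transformation that lets the 2-bit layout feed the same popcount kernels
    as the 3-bit layout: per marker, two blocks are read and the genotype
    blocks are computed on the fly.  Works on plain ints and numpy arrays.
    """
    if isinstance(b1, (int, np.integer)):
        mask = (1 << width) - 1
        b1 = int(b1) & mask
        b2 = int(b2) & mask
    return (b1 & ~b2, b2 & ~b1, b1 & b2)


def expand_2to3(marker: Marker2Bit) -> Marker3Bit:
    """Whole-marker 2-bit -> 3-bit expansion (blockwise mask transform)."""
    bAA, bAa, baa = expand_2to3_block(marker.v1.blocks, marker.v2.blocks)
    n = marker.n
    return Marker3Bit(
        BitVector(bAA, n), BitVector(bAa, n), BitVector(baa, n), n
    )


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


_ENCODERS = {
    "two_bit": encode_2bit,
    "three_bit": encode_3bit,
    "paired": lambda codes, width=64: encode_paired(codes),
}


@dataclass
class GenotypeMatrix:
    """Markers x individuals genotype matrix in one homogeneous encoding.

    Individual indexing is constant across all markers, which is what makes
    cross-marker Boolean counting valid.
    """

    markers: list
    encoding: str
    n: int
    marker_ids: list = field(default_factory=list)
    individual_ids: list = field(default_factory=list)
    width: int = 64

    def __post_init__(self) -> None:
        if self.encoding not in ENCODING_TAGS:
            raise ValueError(f"unknown encoding tag {self.encoding!r}")
        if not self.marker_ids:
            self.marker_ids = [f"M{i + 1}" for i in range(len(self.markers))]
        if not self.individual_ids:
            self.individual_ids = [f"I{i + 1}" for i in range(self.n)]
        for m in self.markers:
            if m.n != self.n:
                raise ValueError("all markers must span the same n individuals")
            if m.encoding != self.encoding:
                raise ValueError("marker encoding does not match the matrix tag")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @classmethod
    def from_codes(
        cls,
        codes,
        encoding: str = "two_bit",
        marker_ids=None,
        individual_ids=None,
        width: int = 64,
    ) -> "GenotypeMatrix":
        """Build a matrix from a (markers x individuals) code/token array."""
        if encoding not in ENCODING_TAGS:
            raise ValueError(f"unknown encoding tag {encoding!r}")
        rows = [as_codes(row) for row in codes]
        if not rows:
            raise ValueError("need at least one marker")
        n = len(rows[0])
        enc = _ENCODERS[encoding]
        markers = [enc(r, width=width) if encoding != "paired" else enc(r) for r in rows]
        return cls(
            markers, encoding, n,
            marker_ids=list(marker_ids) if marker_ids else [],
            individual_ids=list(individual_ids) if individual_ids else [],
            width=width,
        )

    def to_codes(self) -> np.ndarray:
        return np.vstack([decode_codes(m) for m in self.markers])

    def genotype(self, marker_index: int, individual_index: int) -> str:
        return decode(self.markers[marker_index], individual_index)

    def convert(self, target: str) -> "GenotypeMatrix":
        return convert_layout(self, target)


def convert_layout(matrix: GenotypeMatrix, target: str) -> GenotypeMatrix:
    """Genotype-preserving conversion between the three layouts."""
    if target not in ENCODING_TAGS:
        raise ValueError(f"unknown encoding tag {target!r}")
    if target == matrix.encoding:
        return matrix
    if matrix.encoding == "two_bit" and target == "three_bit":
        # pure mask transform, no decode step
        markers = [expand_2to3(m) for m in matrix.markers]
    else:
        codes = [decode_codes(m) for m in matrix.markers]
        enc = _ENCODERS[target]
        markers = [
            enc(c, width=matrix.width) if target != "paired" else enc(c) for c in codes
        ]
    return GenotypeMatrix(
        markers, target, matrix.n,
        marker_ids=list(matrix.marker_ids),
        individual_ids=list(matrix.individual_ids),
        width=matrix.width,
    )
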