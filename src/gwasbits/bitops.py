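"""Fixed-width bit-block primitives.

Everything in this package counts individuals by taking Hamming weights
(population counts) of indicator bit vectors, one bit per individual.  The
reference popcount splits each block into aligned 16-bit half-words and looks
each one up in a precomputed 65,536-entry weight table; an alternative
``native`` path uses the CPU popcount via :func:`numpy.bitwise_count` behind
the same contract.

Bit order is LSB-first: logical individual ``i`` lives in block ``i // W`` at
bit ``i % W``.  Padding bits (logical position >= length) are always zero —
every constructor and mutation re-establishes this, because all counting
correctness depends on it.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np

__all__ = [
    "BitVector",
    "build_weight_table",
    "weight_table",
    "hamming_weight",
    "combined_weight",
    "count_weight_evaluations",
    "ALLOWED_WIDTHS",
]

ALLOWED_WIDTHS = (32, 64)
_DTYPES = {32: np.uint32, 64: np.uint64}
_WIDTH_OF = {np.dtype(np.uint32): 32, np.dtype(np.uint64): 64}

PopcountMethod = Literal["table", "native"]


def build_weight_table() -> np.ndarray:
    """Build the 2^16-entry Hamming-weight lookup table.

    Uses the doubling recurrence ``w[i + 2^k] = w[i] + 1``: after 16 doublings
    entry ``i`` holds the number of set bits in ``i``.  Deterministic.
    """
    w = np.zeros(1, dtype=np.uint8)
    for _ in range(16):
        w = np.concatenate([w, w + 1])
    return w


_WEIGHT_TABLE: np.ndarray | None = None


def weight_table() -> np.ndarray:
    """Return the shared (lazily built) 16-bit weight table."""
    global _WEIGHT_TABLE
    if _WEIGHT_TABLE is None:
        _WEIGHT_TABLE = build_weight_table()
    return _WEIGHT_TABLE


# ---------------------------------------------------------------------------
# instrumentation: count whole-vector weight evaluations
# ---------------------------------------------------------------------------


class EvalCounter:
    """Mutable counter of vector-level Hamming-weight evaluations."""

    __slots__ = ("count",)

    def __init__(self) -> None:
        self.count = 0


_ACTIVE_COUNTERS: list[EvalCounter] = []


@contextmanager
def count_weight_evaluations() -> Iterator[EvalCounter]:
    """Context manager counting how many vector Hamming weights are computed.

    Each call to :func:`hamming_weight` or :func:`combined_weight` counts as
    one evaluation, regardless of vector length.
    """
    c = EvalCounter()
    _ACTIVE_COUNTERS.append(c)
    try:
        yield c
    finally:
        _ACTIVE_COUNTERS.remove(c)


def _tick() -> None:
    for c in _ACTIVE_COUNTERS:
        c.count += 1


# ---------------------------------------------------------------------------
# block-array popcount kernels
# ---------------------------------------------------------------------------


def _popcount_blocks(blocks: np.ndarray, method: PopcountMethod = "table") -> int:
    if method == "native":
        return int(np.bitwise_count(blocks).sum(dtype=np.int64))
    # aligned 16-bit half-words; order of summation is irrelevant
    halves = blocks.view(np.uint16)
    return int(weight_table()[halves].sum(dtype=np.int64))


@dataclass
class BitVector:
    """A length-``length`` logical bit string stored in fixed-width blocks.

    ``blocks`` is a numpy array of uint32 or uint64; the block width W is the
    dtype's bit width.  ``len(blocks) == ceil(length / W)`` and every bit at
    logical position >= ``length`` is zero.
    """

    blocks: np.ndarray
    length: int

    def __post_init__(self) -> None:
        self.blocks = np.ascontiguousarray(self.blocks)
        if self.blocks.dtype not in _WIDTH_OF:
            raise TypeError(f"block dtype must be uint32 or uint64, got {self.blocks.dtype}")
        w = self.width
        expected = -(-self.length // w) if self.length else 0
        if len(self.blocks) != expected:
            raise ValueError(
                f"expected {expected} blocks for length {self.length} at W={w}, "
                f"got {len(self.blocks)}"
            )
        self._zero_padding()

    # -- constructors -------------------------------------------------------

    @classmethod
    def zeros(cls, length: int, width: int = 64) -> "BitVector":
        dtype = _DTYPES[width]
        nblocks = -(-length // width) if length else 0
        return cls(np.zeros(nblocks, dtype=dtype), length)

    @classmethod
    def ones(cls, length: int, width: int = 64) -> "BitVector":
        dtype = _DTYPES[width]
        nblocks = -(-length // width) if length else 0
        v = cls(np.full(nblocks, np.iinfo(dtype).max, dtype=dtype), length)
        return v  # __post_init__ zeroed the padding

    @classmethod
    def from_bools(cls, bits, width: int = 64) -> "BitVector":
        """Pack a boolean sequence LSB-first into blocks."""
        arr = np.asarray(bits, dtype=np.uint8)
        length = len(arr)
        nblocks = -(-length // width) if length else 0
        packed = np.packbits(arr, bitorder="little")
        buf = np.zeros(nblocks * (width // 8), dtype=np.uint8)
        buf[: len(packed)] = packed
        return cls(buf.view(_DTYPES[width]), length)

    @classmethod
    def from_indices(cls, indices, length: int, width: int = 64) -> "BitVector":
        bits = np.zeros(length, dtype=np.uint8)
        bits[np.asarray(indices, dtype=np.intp)] = 1
        return cls.from_bools(bits, width=width)

    # -- structure ----------------------------------------------------------

    @property
    def width(self) -> int:
        return _WIDTH_OF[self.blocks.dtype]

    def _zero_padding(self) -> None:
        """Re-establish the padding-zero rule on the final block."""
        if len(self.blocks) == 0:
            return
        w = self.width
        used = self.length - (len(self.blocks) - 1) * w
        if used < w:
            dtype = self.blocks.dtype
            mask = dtype.type((1 << used) - 1) if used else dtype.type(0)
            self.blocks[-1] &= mask

    def to_bools(self) -> np.ndarray:
        if self.length == 0:
            return np.zeros(0, dtype=bool)
        bits = np.unpackbits(self.blocks.view(np.uint8), bitorder="little")
        return bits[: self.length].astype(bool)

    def get(self, i: int) -> bool:
        if not (0 <= i < self.length):
            raise IndexError(f"bit index {i} out of range for length {self.length}")
        w = self.width
        return bool((int(self.blocks[i // w]) >> (i % w)) & 1)

    def copy(self) -> "BitVector":
        return BitVector(self.blocks.copy(), self.length)

    def equals(self, other: "BitVector") -> bool:
        return (
            self.length == other.length
            and self.width == other.width
            and bool(np.array_equal(self.blocks, other.blocks))
        )

    # -- blockwise boolean algebra (padding stays zero automatically for
    #    AND/ANDNOT/OR of padding-clean operands) ---------------------------

    def _check_compatible(self, other: "BitVector") -> None:
        if self.length != other.length:
            raise ValueError(
                f"incompatible bit vectors: lengths {self.length} != {other.length}"
            )
        if self.width != other.width:
            raise ValueError(
                f"incompatible bit vectors: block widths {self.width} != {other.width}"
            )

    def __and__(self, other: "BitVector") -> "BitVector":
        self._check_compatible(other)
        return BitVector(self.blocks & other.blocks, self.length)

    def __or__(self, other: "BitVector") -> "BitVector":
        self._check_compatible(other)
        return BitVector(self.blocks | other.blocks, self.length)

    def __xor__(self, other: "BitVector") -> "BitVector":
        self._check_compatible(other)
        return BitVector(self.blocks ^ other.blocks, self.length)

    def andnot(self, other: "BitVector") -> "BitVector":
        """Bits set in self but not in other."""
        self._check_compatible(other)
        return BitVector(self.blocks & ~other.blocks, self.length)


# chunk of blocks processed per streaming step; bounds temporary storage
_CHUNK_BLOCKS = 1 << 15


def hamming_weight(v: BitVector, method: PopcountMethod = "table") -> int:
    """Number of set logical bits in ``v`` (requires padding-zero rule)."""
    _tick()
    return _popcount_blocks(v.blocks, method=method)


def combined_weight(
    u: BitVector,
    v: BitVector,
    op: str = "and",
    method: PopcountMethod = "table",
) -> int:
    """Popcount of the blockwise combination of two vectors.

    Streams over the blocks in bounded chunks so no full intermediate vector
    is materialized.  ``op`` is ``"and"`` (u AND v) or ``"andnot"``
    (u AND NOT v).
    """
    u._check_compatible(v)
    if op not in ("and", "andnot"):
        raise ValueError(f"unknown op {op!r}; expected 'and' or 'andnot'")
    _tick()
    total = 0
    for s in range(0, len(u.blocks), _CHUNK_BLOCKS):
        a = u.blocks[s : s + _CHUNK_BLOCKS]
        b = v.blocks[s : s + _CHUNK_BLOCKS]
        c = (a & b) if op == "and" else (a & ~b)
        # padding of u is zero, so ~b cannot leak padding bits into the count
        total += _popcount_blocks(c, method=method)
    return total
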