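"""Readers and writers: text genotype matrix, PLINK 1 BED/BIM/FAM, container.

Text format: a header row of individual ids, then one marker per row — first
column the marker id, remaining whitespace-separated columns one genotype
token per individual (symbolic ``AA/Aa/aa/NN`` or dosage ``0/1/2``, ``.`` or
``-9`` missing).

BED: standard PLINK 1 variant-major layout — magic bytes 0x6C 0x1B, mode
0x01, then per marker ceil(n/4) bytes of bit pairs (00 hom A1, 01 missing,
10 het, 11 hom A2; pairs filled LSB-first).  A1 in the BIM is mapped to the
minor allele "a".  Padding bit pairs in the final byte of each marker are
written as the missing code and never read back (decode is bounded by n).

Container: a single-file format for encoded matrices — magic ``GWBC``, a
JSON header (version, block width, encoding tag, dimensions, ids) and a
DEFLATE-compressed payload of the raw bit blocks; round-trips any matrix
bit-exactly.
"""

from __future__ import annotations

import json
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .bitops import BitVector
from .codec import (
    GenotypeMatrix,
    GenotypeTokenError,
    Marker2Bit,
    Marker3Bit,
    MarkerPaired,
    as_codes,
    codes_to_symbols,
    decode_codes,
    encode_paired,
)
from .tables import PhenotypeSplit

__all__ = [
    "read_text", "write_text",
    "read_bed", "write_bed",
    "save_container", "load_container",
    "MarkerInfo",
]

BED_MAGIC = b"\x6c\x1b"
BED_VARIANT_MAJOR = b"\x01"
CONTAINER_MAGIC = b"GWBC"
CONTAINER_VERSION = 1


class FormatError(ValueError):
    """Malformed on-disk data, reported with location where possible."""


@dataclass
class MarkerInfo:
    """Per-marker metadata carried by BIM files."""

    marker_ids: list
    chromosomes: list = field(default_factory=list)
    positions: list = field(default_factory=list)
    allele1: list = field(default_factory=list)  # minor ("a")
    allele2: list = field(default_factory=list)  # major ("A")

    def __post_init__(self) -> None:
        m = len(self.marker_ids)
        if not self.chromosomes:
            self.chromosomes = ["1"] * m
        if not self.positions:
            self.positions = list(range(1, m + 1))
        if not self.allele1:
            self.allele1 = ["G"] * m
        if not self.allele2:
            self.allele2 = ["A"] * m


# ---------------------------------------------------------------------------
# text matrix format
# ---------------------------------------------------------------------------


def read_text(path, encoding: str = "two_bit", width: int = 64) -> GenotypeMatrix:
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty genotype matrix file")
    individual_ids = lines[0].split()
    n = len(individual_ids)
    rows, marker_ids = [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split()
        if len(fields) != n + 1:
            raise FormatError(
                f"{path}:{lineno}: ragged row for marker {fields[0] if fields else '?'}: "
                f"expected {n} genotype tokens, got {len(fields) - 1}"
            )
        marker_ids.append(fields[0])
        try:
            rows.append(as_codes(fields[1:]))
        except GenotypeTokenError as e:
            raise FormatError(
                f"{path}:{lineno}: {e} (marker {fields[0]})"
            ) from e
    if not rows:
        raise FormatError(f"{path}: no marker rows")
    return GenotypeMatrix.from_codes(
        rows, encoding=encoding, marker_ids=marker_ids,
        individual_ids=individual_ids, width=width,
    )


def write_text(matrix: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(matrix.individual_ids) + "\n")
        for mid, marker in zip(matrix.marker_ids, matrix.markers):
            fh.write("\t".join([mid, *codes_to_symbols(decode_codes(marker))]) + "\n")


# ---------------------------------------------------------------------------
# PLINK BED / BIM / FAM
# ---------------------------------------------------------------------------


def read_bed(
    bed_path, bim_path, fam_path, width: int = 64
) -> tuple[GenotypeMatrix, MarkerInfo, PhenotypeSplit]:
    """Read a PLINK 1 trio into a paired-layout matrix.

    FAM phenotype column: 2 = case, 1 = control, 0/-9 = unassigned
    (unassigned individuals are excluded from both phenotype masks).
    """
    bim_names = ["chrom", "id", "cm", "pos", "a1", "a2"]
    try:
        bim = pd.read_csv(bim_path, sep=r"\s+", header=None, names=bim_names, dtype=str)
    except pd.errors.EmptyDataError:
        bim = pd.DataFrame(columns=bim_names, dtype=str)
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str,
    )
    m, n = len(bim), len(fam)
    raw = Path(bed_path).read_bytes()
    if raw[:2] != BED_MAGIC:
        raise FormatError(f"{bed_path}: bad BED magic bytes {raw[:2]!r}")
    if raw[2:3] != BED_VARIANT_MAJOR:
        raise FormatError(
            f"{bed_path}: unsupported BED mode {raw[2:3]!r} (only variant-major)"
        )
    bpm = -(-n // 4)
    expected = 3 + m * bpm
    if len(raw) != expected:
        raise FormatError(
            f"{bed_path}: payload is {len(raw) - 3} bytes, expected {m} markers x "
            f"{bpm} bytes = {m * bpm} for {n} individuals"
        )
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    markers = [
        MarkerPaired(payload[k * bpm : (k + 1) * bpm].copy(), n) for k in range(m)
    ]
    matrix = GenotypeMatrix(
        markers, "paired", n,
        marker_ids=list(bim["id"]),
        individual_ids=list(fam["iid"]),
        width=width,
    )
    info = MarkerInfo(
        marker_ids=list(bim["id"]),
        chromosomes=list(bim["chrom"]),
        positions=[int(p) for p in bim["pos"]],
        allele1=list(bim["a1"]),
        allele2=list(bim["a2"]),
    )
    pheno = fam["pheno"].to_numpy()
    split = PhenotypeSplit.from_labels(
        pheno == "2", width=width, assigned=np.isin(pheno, ["1", "2"])
    )
    return matrix, info, split


def write_bed(
    matrix: GenotypeMatrix,
    info: Optional[MarkerInfo],
    split: Optional[PhenotypeSplit],
    bed_path,
    bim_path,
    fam_path,
) -> None:
    """Write a variant-major PLINK 1 trio (3 + M*ceil(n/4) BED bytes)."""
    if info is None:
        info = MarkerInfo(marker_ids=list(matrix.marker_ids))
    if len(info.marker_ids) != matrix.n_markers:
        raise FormatError("marker metadata count does not match the matrix")
    with open(bed_path, "wb") as fh:
        fh.write(BED_MAGIC + BED_VARIANT_MAJOR)
        for marker in matrix.markers:
            if isinstance(marker, MarkerPaired):
                fh.write(marker.data.tobytes())
            else:
                fh.write(encode_paired(decode_codes(marker)).data.tobytes())
    with open(bim_path, "w") as fh:
        for k, mid in enumerate(info.marker_ids):
            fh.write(
                f"{info.chromosomes[k]}\t{mid}\t0\t{info.positions[k]}\t"
                f"{info.allele1[k]}\t{info.allele2[k]}\n"
            )
    case = split.case_mask.to_bools() if split is not None else None
    ctrl = split.control_mask.to_bools() if split is not None else None
    with open(fam_path, "w") as fh:
        for i, iid in enumerate(matrix.individual_ids):
            if case is None:
                pheno = "-9"
            elif case[i]:
                pheno = "2"
            elif ctrl[i]:
                pheno = "1"
            else:
                pheno = "0"
            fh.write(f"F{i + 1}\t{iid}\t0\t0\t0\t{pheno}\n")


def write_phenotype_tsv(split: PhenotypeSplit, individual_ids, path) -> None:
    case = split.case_mask.to_bools()
    ctrl = split.control_mask.to_bools()
    with open(path, "w") as fh:
        fh.write("individual\tstatus\n")
        for i, iid in enumerate(individual_ids):
            status = "case" if case[i] else ("control" if ctrl[i] else "unknown")
            fh.write(f"{iid}\t{status}\n")


# ---------------------------------------------------------------------------
# internal compressed container
# ---------------------------------------------------------------------------


def _marker_blocks(marker) -> list[np.ndarray]:
    if isinstance(marker, Marker2Bit):
        return [marker.v1.blocks, marker.v2.blocks]
    if isinstance(marker, Marker3Bit):
        return [marker.s_AA.blocks, marker.s_Aa.blocks, marker.s_aa.blocks]
    if isinstance(marker, MarkerPaired):
        return [marker.data]
    raise TypeError(f"not a marker: {type(marker).__name__}")


def save_container(matrix: GenotypeMatrix, path) -> None:
    """Serialize an encoded matrix bit-exactly with a DEFLATE payload."""
    header = {
        "version": CONTAINER_VERSION,
        "encoding": matrix.encoding,
        "width": matrix.width,
        "n_markers": matrix.n_markers,
        "n_individuals": matrix.n,
        "marker_ids": list(matrix.marker_ids),
        "individual_ids": list(matrix.individual_ids),
    }
    hdr = json.dumps(header, separators=(",", ":")).encode()
    payload = b"".join(
        arr.tobytes() for marker in matrix.markers for arr in _marker_blocks(marker)
    )
    comp = zlib.compress(payload, level=6)
    with open(path, "wb") as fh:
        fh.write(CONTAINER_MAGIC)
        fh.write(struct.pack("<I", len(hdr)))
        fh.write(hdr)
        fh.write(comp)


def load_container(path) -> GenotypeMatrix:
    raw = Path(path).read_bytes()
    if raw[:4] != CONTAINER_MAGIC:
        raise FormatError(f"{path}: bad container magic {raw[:4]!r}")
    (hlen,) = struct.unpack("<I", raw[4:8])
    header = json.loads(raw[8 : 8 + hlen].decode())
    if header.get("version") != CONTAINER_VERSION:
        raise FormatError(f"{path}: unsupported container version {header.get('version')}")
    payload = zlib.decompress(raw[8 + hlen :])
    encoding = header["encoding"]
    width = header["width"]
    n = header["n_individuals"]
    m = header["n_markers"]
    dtype = np.uint32 if width == 32 else np.uint64
    nblocks = -(-n // width)
    vec_bytes = nblocks * (width // 8)
    markers = []
    off = 0

    def take_vec() -> BitVector:
        nonlocal off
        arr = np.frombuffer(payload, dtype=dtype, count=nblocks, offset=off).copy()
        off += vec_bytes
        return BitVector(arr, n)

    for _ in range(m):
        if encoding == "two_bit":
            markers.append(Marker2Bit(take_vec(), take_vec(), n))
        elif encoding == "three_bit":
            markers.append(Marker3Bit(take_vec(), take_vec(), take_vec(), n))
        elif encoding == "paired":
            bpm = -(-n // 4)
            arr = np.frombuffer(payload, dtype=np.uint8, count=bpm, offset=off).copy()
            off += bpm
            markers.append(MarkerPaired(arr, n))
        else:
            raise FormatError(f"{path}: unknown encoding tag {encoding!r}")
    if off != len(payload):
        raise FormatError(f"{path}: trailing bytes in container payload")
    return GenotypeMatrix(
        markers, encoding, n,
        marker_ids=header["marker_ids"],
        individual_ids=header["individual_ids"],
        width=width,
    )
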