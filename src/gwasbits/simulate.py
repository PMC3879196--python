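"""Synthetic genotype data under Hardy-Weinberg equilibrium.

Each marker draws a minor-allele frequency q from a configurable spectrum and
samples genotypes independently per individual with probabilities
((1-q)^2, 2q(1-q), q^2) for (AA, Aa, aa), overwrites genotypes with NN at a
fixed missing rate, and labels individuals case/control at random,
independently of genotype (a pure null — no disease model, no linkage
disequilibrium between markers).

The default spectrum is Beta(0.8, 0.8) rescaled to (0.01, 0.5): a U-shaped
common-variant spectrum of the kind genotyping arrays produce.  It is a
stand-in for array allele-frequency spectra, not a reproduction of any
particular array's.

Reproducibility: one global seed drives a counter-based per-marker substream
(numpy SeedSequence spawn keys), so a matrix is identical regardless of how
generation is chunked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .codec import NN, GenotypeMatrix
from .tables import PhenotypeSplit

__all__ = ["SpectrumSpec", "simulate_matrix", "size_calculator", "size_report"]


@dataclass(frozen=True)
class SpectrumSpec:
    """Minor-allele-frequency spectrum plus missingness and phenotype balance.

    kind: ``uniform`` on (min_maf, max_maf); ``beta`` with (shape1, shape2)
    rescaled to (min_maf, max_maf); or ``empirical`` sampling with replacement
    from a user-supplied MAF list.
    """

    kind: str = "beta"
    min_maf: float = 0.01
    max_maf: float = 0.5
    shape1: float = 0.8
    shape2: float = 0.8
    mafs: Optional[tuple] = None  # for kind="empirical"
    missing_rate: float = 0.0
    case_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "beta", "empirical"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if self.kind == "empirical":
            if not self.mafs:
                raise ValueError("empirical spectrum requires a non-empty MAF list")
            arr = np.asarray(self.mafs, dtype=float)
            if arr.min() <= 0 or arr.max() > 0.5:
                raise ValueError("empirical MAFs must lie in (0, 0.5]")
        else:
            if not (0 < self.min_maf <= self.max_maf <= 0.5):
                raise ValueError("need 0 < min_maf <= max_maf <= 0.5")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must be in (0, 1)")

    def draw_mafs(self, n_markers: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "uniform":
            return rng.uniform(self.min_maf, self.max_maf, n_markers)
        if self.kind == "beta":
            raw = rng.beta(self.shape1, self.shape2, n_markers)
            return self.min_maf + raw * (self.max_maf - self.min_maf)
        return rng.choice(np.asarray(self.mafs, dtype=float), size=n_markers)


def _marker_rng(seed: int, marker_index: int) -> np.random.Generator:
    # counter-based substream: chunk-independent reproducibility
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(marker_index,))
    )


def simulate_matrix(
    n_markers: int,
    n_individuals: int,
    spec: Optional[SpectrumSpec] = None,
    seed: int = 0,
    encoding: str = "two_bit",
    width: int = 64,
) -> tuple[GenotypeMatrix, PhenotypeSplit, np.ndarray]:
    """Simulate an HWE genotype matrix with random case/control labels.

    Returns ``(matrix, split, true_mafs)``; fully reproducible from ``seed``.
    """
    if n_markers < 1 or n_individuals < 1:
        raise ValueError("need at least one marker and one individual")
    if spec is None:
        spec = SpectrumSpec()
    head = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2**31,)))
    mafs = spec.draw_mafs(n_markers, head)
    is_case = head.random(n_individuals) < spec.case_fraction
    codes = np.empty((n_markers, n_individuals), dtype=np.int8)
    for k in range(n_markers):
        rng = _marker_rng(seed, k)
        q = mafs[k]
        u = rng.random(n_individuals)
        # cumulative HWE probabilities: AA, then Aa, then aa
        p_aa_hom_major = (1 - q) ** 2
        p_het = 2 * q * (1 - q)
        row = np.where(
            u < p_aa_hom_major, 1, np.where(u < p_aa_hom_major + p_het, 2, 3)
        ).astype(np.int8)
        if spec.missing_rate > 0:
            row[rng.random(n_individuals) < spec.missing_rate] = NN
        codes[k] = row
    matrix = GenotypeMatrix.from_codes(
        codes,
        encoding=encoding,
        marker_ids=[f"snp{k + 1}" for k in range(n_markers)],
        width=width,
    )
    split = PhenotypeSplit.from_labels(is_case, width=width)
    return matrix, split, mafs


# ---------------------------------------------------------------------------
# storage arithmetic
# ---------------------------------------------------------------------------

_BITS_PER_GENOTYPE = {"two_bit": 2, "three_bit": 3}


def size_calculator(
    n_markers: int,
    n_individuals: int,
    encoding: Optional[str] = None,
    bytes_per_genotype: Optional[float] = None,
    block_width: int = 64,
) -> int:
    """Exact storage in bytes for a markers x individuals genotype matrix.

    Vectored layouts round each indicator vector up to whole blocks of
    ``block_width`` bits; ``paired`` packs 4 genotypes per byte; alternatively
    give ``bytes_per_genotype`` for flat text-like layouts (e.g. 1).
    """
    if n_markers < 0 or n_individuals < 0:
        raise ValueError("dimensions must be nonnegative")
    if bytes_per_genotype is not None:
        return int(math.ceil(n_markers * n_individuals * bytes_per_genotype))
    if encoding in _BITS_PER_GENOTYPE:
        n_vectors = _BITS_PER_GENOTYPE[encoding]
        blocks_per_vector = -(-n_individuals // block_width)
        return n_markers * n_vectors * blocks_per_vector * (block_width // 8)
    if encoding == "paired":
        return n_markers * -(-n_individuals // 4)
    raise ValueError(f"unknown encoding tag {encoding!r}")


def size_report(
    n_markers: int, n_individuals: int, block_width: int = 64
) -> dict[str, float]:
    """Sizes of all layouts plus the 2-bit/3-bit ratio (2/3 at aligned n)."""
    sizes = {
        tag: size_calculator(n_markers, n_individuals, tag, block_width=block_width)
        for tag in ("two_bit", "three_bit", "paired")
    }
    sizes["one_byte"] = size_calculator(
        n_markers, n_individuals, bytes_per_genotype=1
    )
    sizes["two_over_three_ratio"] = (
        sizes["two_bit"] / sizes["three_bit"] if sizes["three_bit"] else float("nan")
    )
    return sizes
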