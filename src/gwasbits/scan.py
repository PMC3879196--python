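"""Exhaustive case/control pairwise scan with a pluggable per-pair statistic.

For M markers the scan builds C(M,2) pairs; for each pair it constructs the
case and control contingency tables (via the marginal reduction whenever both
markers are missing-free in that stratum, else the full nine-popcount table)
and applies the configured statistic.

The default statistic is a log-linear likelihood-ratio interaction test on
the 3x3x2 genotype x genotype x phenotype table: the saturated model against
the model with all two-way associations but no three-way interaction.  The
constrained model has no closed-form fit and is obtained by iterative
proportional fitting (IPF) on the three two-way margins; the deviance
G^2 = 2 * sum n * log(n / mu) is referred to a chi-square with
(r_A - 1)(r_B - 1) degrees of freedom (4 when all three genotype categories
are populated at both markers), where categories empty in both strata are
dropped.  Missing genotypes never enter: the statistic uses the 3x3
non-missing block, so individuals are excluded pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional

import numpy as np
from scipy import stats as _sps

from .codec import GenotypeMatrix
from .tables import (
    ContingencyTable,
    PhenotypeSplit,
    contingency_full,
    contingency_marginal,
    frequency_table,
)

__all__ = [
    "PairResult",
    "ScanConfig",
    "scan_all_pairs",
    "lr_interaction_statistic",
    "pair_count",
    "write_results_tsv",
    "STATISTICS",
]


@dataclass(frozen=True)
class PairResult:
    index_a: int
    index_b: int
    id_a: str
    id_b: str
    statistic: float
    degrees_of_freedom: int
    p_value: float


StatisticFn = Callable[[ContingencyTable, ContingencyTable], tuple[float, int, float]]


def pair_count(m: int) -> int:
    """Number of unordered marker pairs, m(m-1)/2."""
    if m < 0:
        raise ValueError("marker count must be nonnegative")
    return m * (m - 1) // 2


# ---------------------------------------------------------------------------
# log-linear likelihood-ratio interaction statistic
# ---------------------------------------------------------------------------


def _ipf_no_three_way(table: np.ndarray, tol: float = 1e-10, max_iter: int = 500) -> np.ndarray:
    """Fit the no-three-way-interaction log-linear model by IPF.

    ``table`` is (rA, rB, 2) observed counts; returns fitted means matching
    the AB, A-phenotype and B-phenotype two-way margins.
    """
    m_ab = table.sum(axis=2)
    m_ap = table.sum(axis=1)
    m_bp = table.sum(axis=0)
    mu = np.full(table.shape, table.sum() / table.size, dtype=float)
    for _ in range(max_iter):
        prev = mu.copy()
        s = mu.sum(axis=2)
        mu *= np.where(s > 0, m_ab / np.where(s > 0, s, 1.0), 0.0)[:, :, None]
        s = mu.sum(axis=1)
        mu *= np.where(s > 0, m_ap / np.where(s > 0, s, 1.0), 0.0)[:, None, :]
        s = mu.sum(axis=0)
        mu *= np.where(s > 0, m_bp / np.where(s > 0, s, 1.0), 0.0)[None, :, :]
        if np.abs(mu - prev).max() < tol:
            break
    return mu


def lr_interaction_statistic(
    case_table: ContingencyTable, control_table: ContingencyTable
) -> tuple[float, int, float]:
    """Likelihood-ratio test for genotype x genotype x phenotype interaction.

    Returns ``(G2, df, p)``.  Genotype categories with zero counts in both
    strata are removed and df adjusted; no pseudo-counts are added.
    """
    if case_table.n == 0 or control_table.n == 0:
        raise ValueError("empty case or control subset")
    obs = np.stack(
        [case_table.nonmissing(), control_table.nonmissing()], axis=2
    ).astype(float)
    keep_a = obs.sum(axis=(1, 2)) > 0
    keep_b = obs.sum(axis=(0, 2)) > 0
    obs = obs[keep_a][:, keep_b]
    ra, rb = obs.shape[0], obs.shape[1]
    df = (ra - 1) * (rb - 1)
    if df <= 0:
        return (0.0, 0, 1.0)
    mu = _ipf_no_three_way(obs)
    pos = obs > 0
    g2 = 2.0 * float(np.sum(obs[pos] * np.log(obs[pos] / mu[pos])))
    g2 = max(g2, 0.0)  # guard tiny negative rounding
    p = float(_sps.chi2.sf(g2, df))
    return (g2, df, p)


def _no_statistic(
    case_table: ContingencyTable, control_table: ContingencyTable
) -> tuple[float, int, float]:
    """Counting-only plug-in: build the tables, report no test."""
    return (0.0, 0, 1.0)


STATISTICS: dict[str, StatisticFn] = {
    "loglinear": lr_interaction_statistic,
    "none": _no_statistic,
}


@dataclass
class ScanConfig:
    """Scan settings: statistic plug-in, reporting threshold, block width."""

    statistic: str = "loglinear"
    p_threshold: float = 1.0  # report everything by default
    width: int = 64

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_threshold <= 1.0:
            raise ValueError("p_threshold must be in [0, 1]")
        if self.statistic not in STATISTICS:
            raise ValueError(
                f"unknown statistic {self.statistic!r}; known: {sorted(STATISTICS)}"
            )


def _pair_tables(
    matrix: GenotypeMatrix,
    split: PhenotypeSplit,
    i: int,
    j: int,
    freqs_case,
    freqs_ctrl,
    width: int,
) -> tuple[ContingencyTable, ContingencyTable]:
    a, b = matrix.markers[i], matrix.markers[j]
    case = contingency_marginal(
        a, b, freqs_case[i], freqs_case[j], split.case_mask, width
    ).table
    ctrl = contingency_marginal(
        a, b, freqs_ctrl[i], freqs_ctrl[j], split.control_mask, width
    ).table
    return case, ctrl


def scan_all_pairs(
    matrix: GenotypeMatrix,
    split: PhenotypeSplit,
    config: Optional[ScanConfig] = None,
) -> Iterator[PairResult]:
    """Yield one PairResult per unordered marker pair, (a, b) lexicographic.

    Per-marker per-stratum frequency tables are computed once up front; each
    pair then costs four direct popcounts per stratum on missing-free data.
    Results are independent of the storage layout and block width.
    """
    if config is None:
        config = ScanConfig()
    m = matrix.n_markers
    if m < 2:
        raise ValueError("scan requires at least 2 markers")
    if split.n != matrix.n:
        raise ValueError(
            f"phenotype split covers {split.n} individuals, matrix has {matrix.n}"
        )
    stat_fn = STATISTICS[config.statistic]
    freqs_case = [
        frequency_table(mk, split.case_mask, width=config.width) for mk in matrix.markers
    ]
    freqs_ctrl = [
        frequency_table(mk, split.control_mask, width=config.width)
        for mk in matrix.markers
    ]
    for i in range(m - 1):
        for j in range(i + 1, m):
            case, ctrl = _pair_tables(
                matrix, split, i, j, freqs_case, freqs_ctrl, config.width
            )
            g2, df, p = stat_fn(case, ctrl)
            if p <= config.p_threshold:
                yield PairResult(
                    i, j, matrix.marker_ids[i], matrix.marker_ids[j], g2, df, p
                )


def write_results_tsv(results, path) -> int:
    """Stream PairResults to a TSV file; returns the number of rows written."""
    n = 0
    with open(path, "w") as fh:
        fh.write("index_a\tid_a\tindex_b\tid_b\tstatistic\tdf\tp_value\n")
        for r in results:
            fh.write(
                f"{r.index_a}\t{r.id_a}\t{r.index_b}\t{r.id_b}\t"
                f"{r.statistic:.6g}\t{r.degrees_of_freedom}\t{r.p_value:.6g}\n"
            )
            n += 1
    return n
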