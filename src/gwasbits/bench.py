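"""Benchmark harness comparing the 2-bit and 3-bit counting paths.

Three workloads per encoding on the same simulated data: per-marker
case/control frequency tables, all-pairs contingency tables, and the full
scan with the default interaction statistic (scan timing excludes data
generation and encoding).  Before any time is reported, the harness verifies
that both encodings produce cell-identical counts — the encodings are
different storage layouts of the same information, so timings without that
attestation would be meaningless.

Timing uses the monotonic high-resolution clock; a warm-up repetition is
discarded, timer overhead is estimated and subtracted from per-table
averages, and mean is reported alongside median and IQR.  Absolute times are
hardware-bound and are not stable quantities; the harness reproduces the
comparison's structure, not any particular machine's numbers.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .codec import GenotypeMatrix, convert_layout
from .scan import ScanConfig, pair_count, scan_all_pairs
from .simulate import SpectrumSpec, simulate_matrix, size_calculator
from .tables import contingency_full, frequency_table

__all__ = ["BenchScenario", "BenchReport", "run_benchmark", "report_to_tsv"]

WORKLOADS = ("frequency", "contingency", "scan")


@dataclass
class BenchScenario:
    n_markers: int = 200
    n_individuals: Sequence[int] = (500, 1000, 2000)
    encodings: Sequence[str] = ("two_bit", "three_bit")
    repetitions: int = 3
    seed: int = 0
    spec: Optional[SpectrumSpec] = None
    memory_budget_bytes: int = 2 << 30

    def __post_init__(self) -> None:
        if self.repetitions < 3:
            raise ValueError("repetitions must be >= 3 for any reported mean")
        if self.n_markers < 2:
            raise ValueError("need at least 2 markers")


@dataclass
class BenchReport:
    rows: list  # dicts: workload, encoding, n, mean_s, median_s, iqr_s, per_table_us
    attestation_passed: bool
    timer_overhead_s: float


def _timer_overhead(reps: int = 2000) -> float:
    t0 = time.perf_counter()
    for _ in range(reps):
        time.perf_counter()
    return (time.perf_counter() - t0) / reps


def _workload_frequency(matrix: GenotypeMatrix, split) -> list:
    out = []
    for m in matrix.markers:
        out.append(frequency_table(m, split.case_mask).as_tuple())
        out.append(frequency_table(m, split.control_mask).as_tuple())
    return out


def _workload_contingency(matrix: GenotypeMatrix, split) -> int:
    # all-pairs case/control tables; fold cells into a checksum so the
    # attestation can compare encodings without holding every table
    acc = 0
    markers = matrix.markers
    for i in range(len(markers) - 1):
        for j in range(i + 1, len(markers)):
            for mask in (split.case_mask, split.control_mask):
                t = contingency_full(markers[i], markers[j], mask, matrix.width)
                acc = (acc * 1000003 + int(t.cells.sum()) + int((t.cells**2).sum())) % (1 << 61)
    return acc


def _workload_scan(matrix: GenotypeMatrix, split) -> list:
    cfg = ScanConfig(width=matrix.width)
    return [
        (r.index_a, r.index_b, round(r.statistic, 9))
        for r in scan_all_pairs(matrix, split, cfg)
    ]


_WORKLOAD_FNS = {
    "frequency": _workload_frequency,
    "contingency": _workload_contingency,
    "scan": _workload_scan,
}


def run_benchmark(s: BenchScenario) -> BenchReport:
    """Run all three workloads for every (encoding, cohort size) setting."""
    worst = max(s.n_individuals)
    need = size_calculator(s.n_markers, worst, "three_bit")
    if need > s.memory_budget_bytes:
        raise MemoryError(
            f"scenario needs about {need} bytes for the 3-bit matrix alone, "
            f"budget is {s.memory_budget_bytes}"
        )
    overhead = _timer_overhead()
    rows: list[dict] = []
    attested = True
    for n in s.n_individuals:
        base, split, _ = simulate_matrix(
            s.n_markers, n, spec=s.spec, seed=s.seed, encoding="two_bit"
        )
        matrices = {tag: convert_layout(base, tag) for tag in s.encodings}
        for workload in WORKLOADS:
            fn = _WORKLOAD_FNS[workload]
            reference = None
            n_tables = (
                2 * s.n_markers
                if workload == "frequency"
                else 2 * pair_count(s.n_markers)
            )
            for tag, matrix in matrices.items():
                result = fn(matrix, split)  # warm-up, also the attestation run
                if reference is None:
                    reference = result
                elif result != reference:
                    attested = False
                times = []
                for _ in range(s.repetitions):
                    t0 = time.perf_counter()
                    fn(matrix, split)
                    times.append(time.perf_counter() - t0 - overhead)
                times_arr = np.asarray(times)
                q1, med, q3 = np.percentile(times_arr, [25, 50, 75])
                rows.append(
                    {
                        "workload": workload,
                        "encoding": tag,
                        "n_individuals": n,
                        "mean_s": float(times_arr.mean()),
                        "median_s": float(med),
                        "iqr_s": float(q3 - q1),
                        "per_table_us": float(times_arr.mean() / n_tables * 1e6),
                    }
                )
    if not attested:
        raise RuntimeError(
            "cross-encoding attestation failed: encodings disagreed on counts"
        )
    return BenchReport(rows, attested, overhead)


def report_to_tsv(report: BenchReport, path) -> None:
    cols = ["workload", "encoding", "n_individuals", "mean_s", "median_s", "iqr_s", "per_table_us"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in report.rows:
            fh.write("\t".join(str(r[c]) for c in cols) + "\n")


def plot_report(report: BenchReport, path) -> None:
    """Mean time vs cohort size, one panel per workload (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(WORKLOADS), figsize=(4 * len(WORKLOADS), 3.2))
    for ax, workload in zip(np.atleast_1d(axes), WORKLOADS):
        for tag in sorted({r["encoding"] for r in report.rows}):
            pts = sorted(
                (r["n_individuals"], r["mean_s"])
                for r in report.rows
                if r["workload"] == workload and r["encoding"] == tag
            )
            ax.plot([p[0] for p in pts], [p[1] for p in pts], marker="o", label=tag)
        ax.set_title(workload)
        ax.set_xlabel("individuals")
        ax.set_ylabel("mean time (s)")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
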