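# Methods

## Data model

A genotype matrix is markers × individuals over the alphabet
{AA, Aa, aa, NN}, with A the major and a the minor allele, heterozygote
phase collapsed, and NN meaning missing. Individual indexing is constant
across markers; this is what makes cross-marker Boolean counting valid.
Three storage layouts carry the same information:

* **two_bit** — per marker, two bit vectors: v1 flags {AA, aa}, v2 flags
  {Aa, aa}. The code map NN=(0,0), AA=(1,0), Aa=(0,1), aa=(1,1) is chosen so
  that `v1 AND v2` is exactly the aa indicator, which is what makes the
  three-weight frequency algorithm work. Internal genotype codes are
  NN=0, AA=1, Aa=2, aa=3, so the 2-bit layout is a literal bit-slice of the
  code (low bit → v1, high bit → v2).
* **three_bit** — one indicator stream per non-missing class; the streams
  are mutually exclusive and missing is all-clear.
* **paired** — PLINK 1 BED convention: an individual's two bits are adjacent
  (00 hom A1 = aa, 01 missing, 10 het, 11 hom A2 = AA), four individuals per
  byte, pairs filled LSB-first. A1 from a BIM file maps to the minor allele.

Bit order in the vectored layouts is LSB-first within blocks of W ∈ {32, 64}
bits (default 64). All padding bits beyond the cohort size are kept zero and
re-zeroed after any mutation; every counting guarantee depends on this rule.

## Counting algorithms

Popcount splits each block into aligned 16-bit half-words and sums lookups
in a precomputed 2¹⁶-entry weight table (built once by the doubling
recurrence `w[i + 2^k] = w[i] + 1`). A `native` path using the hardware
popcount instruction (via `numpy.bitwise_count`) sits behind the same
contract; the lookup table is the reference. `combined_weight` fuses the
Boolean combine with the count, streaming over blocks in bounded chunks.

Frequency table, 2-bit path: exactly three vector weights (w1, w2,
|v1 AND v2|); the missing count follows by subtraction from the subset size.
3-bit path: one weight per stream. Subset restriction (case/control) is an
AND with a membership mask — the matrix is never duplicated per phenotype
group.

Contingency table, full path: the 3×3 non-missing block is nine popcounts of
stream ANDs; for 2-bit input the streams are derived blockwise by the mask
transform (aa = v1∧v2, AA = v1∧¬v2, Aa = v2∧¬v1). The NN row and column are
completed by subtracting computed row/column sums from the two per-marker
marginals, and (NN,NN) by subtraction from the subset size — no explicit
missing stream is ever materialized. The cell accumulations are vectorized
numpy reductions per stream pair; since the cells are order-independent
integer sums, this is count-identical to a per-block fused loop.

Marginal reduction: with per-marker frequency tables in hand and **no
missing genotypes in the counted subset**, only the four cells (AA,AA),
(AA,Aa), (Aa,AA), (Aa,Aa) are popcounted; the remaining five non-missing
cells follow from the marginals. With missing data, 4 computed cells plus
the 7 independent marginal constraints underdetermine the 16-cell table, so
`contingency_marginal` falls back to the full path and reports that it did
(`used_fallback`), rather than silently return approximate counts. An
instrumentation context manager counts vector-level weight evaluations so
the 9-vs-4 claim is testable, not just asserted.

## Interaction statistic

The scan's default per-pair statistic is a likelihood-ratio test comparing
the saturated log-linear model of the 3×3×2 genotype×genotype×phenotype
table against the model with all two-way associations but no three-way
interaction. The constrained fit has no closed form and is computed by
iterative proportional fitting on the three two-way margins (tolerance
1e-10, cap 500 sweeps); the deviance G² = 2Σ n log(n/μ) is referred to a
chi-square with (r_A−1)(r_B−1) degrees of freedom — 4 when all three
genotype classes are present at both markers. Genotype classes empty in both
strata are dropped and df reduced; no pseudo-counts are added, a choice that
avoids bias at the cost of conservative behaviour on very sparse tables
(plug-in statistics may choose differently). Missing genotypes never enter
the statistic (the 3×3 block excludes them), so individuals are dropped
pairwise. The engine applies no multiple-testing correction; the reporting
threshold is a raw p-value filter. A `none` statistic runs the scan as pure
table construction, which is the configuration whose runtime scales with
cohort size (the likelihood fit itself costs O(1) in n and, in this Python
implementation, dominates at small cohorts).

## Simulator

Per marker, a minor-allele frequency q is drawn from a configurable
spectrum; genotypes are sampled independently per individual under
Hardy–Weinberg equilibrium — probabilities ((1−q)², 2q(1−q), q²) — then
overwritten with NN at a fixed `missing_rate` (default 0), and individuals
are labelled case with probability `case_fraction` (default 0.5),
independent of genotype. The default spectrum is Beta(0.8, 0.8) rescaled to
(0.01, 0.5): a U-shaped common-variant spectrum of the sort genotyping
arrays yield. It is a synthetic stand-in, not a reproduction of any
particular array's empirical spectrum; uniform and user-supplied empirical
MAF lists are alternatives. Reproducibility is counter-based: one global
seed spawns an independent substream per marker, so marker k's genotypes do
not depend on how many markers were requested.

What the simulator deliberately omits: linkage disequilibrium between
markers, any genotype–phenotype association (pure null), and population
structure. Passing tests therefore demonstrate counting and statistical
calibration under independence, not power or robustness on structured real
cohorts.

## Storage arithmetic

`size_calculator` reports exact bytes: vectored layouts round each indicator
vector up to whole W-bit blocks (so 2n vs 3n bits per marker, a ratio of
exactly 2/3 whenever n is a multiple of W), the paired layout packs four
genotypes per byte, and a `bytes_per_genotype` option covers flat text-like
storage (at 1 byte per genotype, 36.7 million variants × 1,000 individuals
is 36.7 GB — the motivating number for succinct layouts).

## Benchmark harness

Three workloads per encoding on identical simulated data: per-marker
case/control frequency tables, all-pairs contingency tables, and the full
scan (timed after data generation and encoding). Before any timing is
reported the harness verifies both encodings produced identical counts;
disagreement aborts the report. Timing uses the monotonic high-resolution
clock, discards a warm-up repetition, subtracts measured timer overhead,
and reports mean together with median and IQR (means alone are fragile on
shared machines); at least 3 repetitions are required. Absolute and relative
times are hardware-bound and are not asserted anywhere — the tests check
structure (report completeness, attestation) and the qualitative property
that counting-only scan time grows monotonically with cohort size.

## Numerical and design choices

* W = 64 default (32 supported, results invariant); 16-bit lookups on
  aligned half-words.
* Text dialects: symbolic AA/Aa/aa/NN and minor-allele dosage 0/1/2 with
  "." or "-9" missing.
* BED padding bit-pairs are written as the missing code and ignored on read
  (decode is bounded by n), so padding can never perturb a count after
  layout conversion.
* The container format compresses the raw bit blocks with DEFLATE; its
  contract is bit-exact round-trip, not any particular codec or ratio.
* Degenerate inputs: empty genotype sequences are rejected at encode time;
  an all-zero subset mask yields an all-zero table with n=0; an empty case
  or control stratum is an error for the statistic.

## Test problem sizes

The suite runs everything at desk scale: oracle comparisons at n ≤ 2,000
individuals, cross-encoding equality on 100 random datasets, null
calibration of the interaction test at 2,000 replicates of n = 2,000
(Kolmogorov–Smirnov distance to uniform below 0.05), and the scan
monotonicity ladder at n = 2,000 / 32,000 / 256,000 with 25 markers. These
sizes were chosen so the full suite completes in well under a minute while
each property is still measured in the regime it concerns.
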