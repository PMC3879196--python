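# gwasbits

Succinct bit-packed genotype data structures for case/control GWAS counting.

Genome-scale association studies spend most of their inner-loop time counting
genotypes: per-marker frequency tables for single-variant tests, and 4×4
pairwise genotype count (contingency) tables for exhaustive epistasis scans —
m(m−1)/2 of them, about 5×10⁷ tables for 10,000 markers and 5×10¹¹ for a
million. `gwasbits` stores biallelic unphased genotypes {AA, Aa, aa, NN} as
indicator bit vectors, one bit per individual, so that every count becomes a
Hamming weight (popcount) of a Boolean combination of vectors, and a whole
processor word of individuals is counted per instruction.

Two vectored layouts are provided and compared:

* **3-bit**: one indicator stream per non-missing genotype class
  (s_AA, s_Aa, s_aa); missing is the all-clear code. Each contingency cell is
  `popcount(s_x(A) AND s_y(B))`.
* **2-bit** (the information-theoretic bound for a 4-symbol alphabet, one
  third less memory): v1 flags {AA, aa}, v2 flags {Aa, aa}. A frequency table
  needs only three weights — w1 = |v1|, w2 = |v2|, w3 = |v1 AND v2| — since
  n_aa = w3, n_AA = w1 − w3, n_Aa = w2 − w3. For pairwise counting the three
  genotype streams are recovered blockwise on the fly:
  `aa = v1 AND v2`, `AA = v1 AND NOT v2`, `Aa = v2 AND NOT v1`.

When both markers are missing-free, the **marginal reduction** builds a
contingency table from only 4 direct popcounts — cells (AA,AA), (AA,Aa),
(Aa,AA), (Aa,Aa) — deriving the other five non-missing cells by subtracting
row/column sums from the per-marker marginals. With missing data the
reduction is underdetermined and the library automatically falls back to the
full nine-popcount table (and says so) rather than return approximate counts.

Popcounts use a precomputed 65,536-entry weight table over aligned 16-bit
half-words (a CPU `popcnt` path is available behind the same contract).
Case/control restriction is a single AND with a phenotype membership mask, so
the matrix is stored once. The PLINK 1 BED paired-bit layout is supported for
interoperability, along with a plain-text matrix format, an internal
compressed container, an exhaustive pairwise scan with a pluggable per-pair
statistic (default: a df-4 log-linear likelihood-ratio interaction test on
the 3×3×2 genotype×genotype×phenotype table), a Hardy–Weinberg simulator,
and a benchmark harness comparing the 2-bit and 3-bit paths.

## Worked example

Five individuals, two markers: M_A = (AA, Aa, AA, aa, NN),
M_B = (AA, AA, aa, aa, Aa).

```python
from gwasbits import encode_2bit, frequency_table_2bit, contingency_full

ma = encode_2bit(["AA", "Aa", "AA", "aa", "NN"])
mb = encode_2bit(["AA", "AA", "aa", "aa", "Aa"])
print("M_A v1:", ma.v1.to_bools().astype(int), " v2:", ma.v2.to_bools().astype(int))
print("freq(M_A):", frequency_table_2bit(ma).as_tuple())
print("freq(M_B):", frequency_table_2bit(mb).as_tuple())
print(contingency_full(ma, mb).to_tsv())
```

prints

```
M_A v1: [1 0 1 1 0]  v2: [0 1 0 1 0]
freq(M_A): (2, 1, 1, 1)
freq(M_B): (2, 1, 2, 0)
	AA	Aa	aa	NN	C_A
AA	1	0	1	0	2
Aa	1	0	0	0	1
aa	0	0	1	0	1
NN	0	1	0	0	1
C_B	2	1	2	0	5
```

`v1`/`v2` are the two indicator vectors of M_A; the frequency tuples are
(n_AA, n_Aa, n_aa, n_NN) — M_A has two AA, one Aa, one aa and one missing
individual. The 4×4 table counts joint genotypes for the pair (one
individual is AA at both markers, one is AA at M_A and aa at M_B, …); its
row and column marginals C_A and C_B reproduce the two frequency tables, and
the NN row/column was filled in by marginal subtraction rather than by
storing an explicit missing stream.

The same operations are available from the shell:

```sh
gwasbits simulate --markers 10 --individuals 1000 --seed 1 --format bed --out cohort
gwasbits freq --in cohort.bed --format bed --by-phenotype
gwasbits scan --in cohort.bed --out results.tsv
gwasbits bench --markers 200 --individuals 1000,2000,4000 --out bench.tsv
```

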