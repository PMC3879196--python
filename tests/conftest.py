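"""Shared fixtures: the five-individual worked example and naive oracles.

The two-marker example (M_A, M_B over individuals I1..I5) exercises every
genotype symbol including missing, and its frequency/contingency tables are
known by hand.  The oracle helpers count genotypes with plain per-individual
Python loops, independent of the bit-vector machinery they check.
"""

import numpy as np
import pytest

from gwasbits.codec import as_codes

M_A_GENOTYPES = ("AA", "Aa", "AA", "aa", "NN")
M_B_GENOTYPES = ("AA", "AA", "aa", "aa", "Aa")

# hand-tallied tables for the example pair
M_A_FREQ = (2, 1, 1, 1)  # AA, Aa, aa, NN
M_B_FREQ = (2, 1, 2, 0)
PAIR_CELLS = np.array(
    [  # rows = M_A genotype, cols = M_B genotype, order AA/Aa/aa/NN
        [1, 0, 1, 0],
        [1, 0, 0, 0],
        [0, 0, 1, 0],
        [0, 1, 0, 0],
    ]
)


@pytest.fixture
def marker_a_genotypes():
    return M_A_GENOTYPES


@pytest.fixture
def marker_b_genotypes():
    return M_B_GENOTYPES


@pytest.fixture
def rng():
    return np.random.default_rng(20130369)


# ---------------------------------------------------------------------------
# naive loop oracles (deliberately bit-free)
# ---------------------------------------------------------------------------

ORDER = ("AA", "Aa", "aa", "NN")
_CODE_TO_ORDER = {1: 0, 2: 1, 3: 2, 0: 3}  # internal code -> table position


def oracle_frequency(genotypes, mask=None):
    """Per-individual loop count of (AA, Aa, aa, NN) within a boolean mask."""
    codes = as_codes(genotypes)
    counts = [0, 0, 0, 0]
    for i, c in enumerate(codes):
        if mask is not None and not mask[i]:
            continue
        counts[_CODE_TO_ORDER[int(c)]] += 1
    return tuple(counts)


def oracle_contingency(genos_a, genos_b, mask=None):
    """Per-individual double tally of the 4x4 joint genotype table."""
    ca, cb = as_codes(genos_a), as_codes(genos_b)
    assert len(ca) == len(cb)
    cells = np.zeros((4, 4), dtype=np.int64)
    for i in range(len(ca)):
        if mask is not None and not mask[i]:
            continue
        cells[_CODE_TO_ORDER[int(ca[i])], _CODE_TO_ORDER[int(cb[i])]] += 1
    return cells


def oracle_popcount_bits(bits) -> int:
    return sum(1 for b in bits if b)


def random_genotypes(rng, n, missing_rate=0.1):
    """Random genotype code array including missing values."""
    codes = rng.integers(1, 4, size=n).astype(np.int8)
    codes[rng.random(n) < missing_rate] = 0
    return codes
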