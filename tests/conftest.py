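"""Shared fixtures and independent oracles.

The oracles recompute the LD statistics from first principles — Pearson
correlations of binary indicator vectors via numpy.corrcoef — with no code
shared with the implementation under test.
"""

from __future__ import annotations

import itertools
from typing import Optional, Tuple

import numpy as np
import pytest

from ldgwas import worked_example_fixture


@pytest.fixture
def toy():
    """The 8-haplotype, 2-SNP, 4-sample worked example."""
    return worked_example_fixture()


def pearson(x: np.ndarray, y: np.ndarray) -> Optional[float]:
    """Pearson correlation of two vectors; None if either is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def oracle_single(alleles: np.ndarray, codes: np.ndarray) -> Optional[float]:
    """Independent single-SNP r: correlation of the alternate-allele
    indicator with the case indicator over usable haplotype observations."""
    a = np.asarray(alleles)
    status = np.repeat(np.asarray(codes), 2)
    mask = (a >= 0) & (status >= 0)
    if not mask.any():
        return None
    return pearson((a[mask] == 1).astype(float), (status[mask] == 1).astype(float))


def oracle_pair(
    a: np.ndarray, b: np.ndarray, codes: np.ndarray
) -> Tuple[Optional[float], Optional[Tuple[int, int, int]]]:
    """Independent pair statistic: brute-force maximum over the 8 (i, j, k)
    combinations of the Pearson correlation between the (A_i ∧ B_j)
    haplotype indicator and the C_k status indicator. Ties broken by
    lexicographic (i, j, k); returns (max r, argmax combo)."""
    a = np.asarray(a)
    b = np.asarray(b)
    status = np.repeat(np.asarray(codes), 2)
    mask = (a >= 0) & (b >= 0) & (status >= 0)
    if not mask.any():
        return None, None
    av, bv, sv = a[mask], b[mask], status[mask]
    best, combo = None, None
    for i, j, k in itertools.product((1, 2), repeat=3):
        ind_ab = ((av == (1 if i == 1 else 0)) & (bv == (1 if j == 1 else 0))).astype(
            float
        )
        ind_c = (sv == (1 if k == 1 else 0)).astype(float)
        r = pearson(ind_ab, ind_c)
        if r is None:
            continue
        if best is None or r > best:
            best, combo = r, (i, j, k)
    return best, combo


def oracle_pair_value(
    a: np.ndarray, b: np.ndarray, codes: np.ndarray, combo: Tuple[int, int, int]
) -> Optional[float]:
    """Oracle indicator-Pearson value for one specific (i, j, k) combo."""
    a = np.asarray(a)
    b = np.asarray(b)
    status = np.repeat(np.asarray(codes), 2)
    mask = (a >= 0) & (b >= 0) & (status >= 0)
    i, j, k = combo
    ind_ab = (
        (a[mask] == (1 if i == 1 else 0)) & (b[mask] == (1 if j == 1 else 0))
    ).astype(float)
    ind_c = (status[mask] == (1 if k == 1 else 0)).astype(float)
    return pearson(ind_ab, ind_c)


def random_single_instance(rng: np.random.Generator, max_samples: int = 25):
    """A random small instance: haplotype alleles (with missing) and
    per-sample status codes (with unknowns)."""
    n = int(rng.integers(2, max_samples + 1))
    alleles = rng.choice([0, 1, -1], size=2 * n, p=[0.45, 0.45, 0.1]).astype(np.int8)
    codes = rng.choice([1, 0, -1], size=n, p=[0.4, 0.4, 0.2]).astype(np.int8)
    return alleles, codes


def random_pair_instance(rng: np.random.Generator, max_samples: int = 25):
    n = int(rng.integers(2, max_samples + 1))
    a = rng.choice([0, 1, -1], size=2 * n, p=[0.45, 0.45, 0.1]).astype(np.int8)
    b = rng.choice([0, 1, -1], size=2 * n, p=[0.45, 0.45, 0.1]).astype(np.int8)
    codes = rng.choice([1, 0, -1], size=n, p=[0.4, 0.4, 0.2]).astype(np.int8)
    return a, b, codes
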