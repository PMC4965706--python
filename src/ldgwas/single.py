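"""Single-SNP association via linkage disequilibrium with the phenotype.

The phenotype is treated as a second locus: over haplotype observations
(two per phenotyped individual), the classical LD covariance

    D = p(A1 ∧ case) − p(A1) · p(case)

is normalized to the Pearson correlation of the two binary indicators,

    r = D / sqrt(p(A1) p(A2) p(case) p(control)),

and r² is the association score. r² = 1 means allele and case status always
co-occur. All probabilities are observed (maximum-likelihood) frequencies
over the included haplotype observations; unknown-status samples and
missing alleles are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np

from ._util import chrom_sort_key
from .errors import InputError
from .io import CASE, CONTROL, HaplotypeMatrix, PhenotypeVector, SNPRecord

PhenoLike = Union[PhenotypeVector, np.ndarray, Sequence[int]]


def _status_codes(pheno: PhenoLike) -> np.ndarray:
    if isinstance(pheno, PhenotypeVector):
        return pheno.codes
    return np.asarray(pheno, dtype=np.int8)


@dataclass
class SingleLDResult:
    """LD between one SNP's alleles and case/control status.

    ``counts`` is a 2×2 table indexed [allele][status] with allele 0 = A1
    (alternate-like), 1 = A2, and status 0 = case, 1 = control.
    """

    snp: Optional[SNPRecord]
    D: float
    r: float
    r2: float
    counts: np.ndarray
    n_obs: int
    degenerate: bool = False
    reported: bool = False


def single_snp_ld(
    alleles: Sequence[int], pheno: PhenoLike, snp: Optional[SNPRecord] = None
) -> SingleLDResult:
    """Compute D, r and r² between one SNP and case/control status.

    ``alleles`` holds haplotype allele codes, two per sample (0/1, -1
    missing), in the same sample order as ``pheno``. Each non-missing
    haplotype of a phenotyped sample contributes one (allele, status)
    observation. Monomorphic SNPs or single-class phenotypes give a
    degenerate result with r = r² = 0 rather than an error, so scans never
    abort on uninformative sites.
    """
    a = np.asarray(alleles, dtype=np.int8)
    codes = _status_codes(pheno)
    if a.shape[0] != 2 * codes.shape[0]:
        raise InputError(
            f"expected {2 * codes.shape[0]} haplotype alleles, got {a.shape[0]}"
        )
    status_h = np.repeat(codes, 2)
    mask = (a >= 0) & (status_h >= 0)
    n = int(mask.sum())
    counts = np.zeros((2, 2), dtype=np.int64)
    if n == 0:
        return SingleLDResult(snp, 0.0, 0.0, 0.0, counts, 0, degenerate=True)

    av = a[mask]
    case = status_h[mask] == CASE
    counts[0, 0] = int(np.sum((av == 1) & case))
    counts[0, 1] = int(np.sum((av == 1) & ~case))
    counts[1, 0] = int(np.sum((av == 0) & case))
    counts[1, 1] = int(np.sum((av == 0) & ~case))

    # Integer-count forms of D = p(A1∧case) − p(A1)p(case) and the Pearson
    # denominator: exact under allele/phenotype relabeling (the numerator
    # negates and the radicand is invariant as integers).
    c11, c12 = int(counts[0, 0]), int(counts[0, 1])
    c21, c22 = int(counts[1, 0]), int(counts[1, 1])
    num = c11 * c22 - c12 * c21
    D = num / (n * n)
    radicand = (c11 + c12) * (c21 + c22) * (c11 + c21) * (c12 + c22)
    if radicand <= 0:
        return SingleLDResult(snp, D, 0.0, 0.0, counts, n, degenerate=True)
    r = num / math.sqrt(radicand)
    return SingleLDResult(snp, D, r, r * r, counts, n, degenerate=False)


def single_scan(
    matrix: HaplotypeMatrix, pheno: PhenotypeVector, min_r2: float = 0.025
) -> List[SingleLDResult]:
    """Scan every SNP against the phenotype; runtime O(samples × SNPs).

    Returns one result per SNP ordered by (chrom, pos), with ``reported``
    set on results reaching ``min_r2``.
    """
    if list(pheno.samples) != list(matrix.samples):
        raise InputError("phenotype samples do not match genotype samples")
    order = sorted(
        range(matrix.n_snps),
        key=lambda i: (
            chrom_sort_key(matrix.snps[i].chrom),
            matrix.snps[i].pos,
            matrix.snps[i].id,
        ),
    )
    results: List[SingleLDResult] = []
    for i in order:
        res = single_snp_ld(matrix.snp_alleles(i), pheno, snp=matrix.snps[i])
        res.reported = res.r2 >= min_r2
        results.append(res)
    return results
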