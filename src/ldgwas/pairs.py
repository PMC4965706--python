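"""Pairwise (epistasis) scan: LD between a SNP pair and the phenotype.

For two SNPs A and B and the phenotype C, the joint statistic considers all
eight allele/status combinations (i, j, k) ∈ {1, 2}³:

    D_{ijk} = p(A_i ∧ B_j ∧ C_k) − p(A_i B_j) · p(C_k)
    d_{ijk} = sqrt( p(A_i B_j) · (1 − p(A_i B_j)) · p(C1) · p(C2) )
    r       = max_{ijk} ( D_{ijk} / d_{ijk} ),   r² = r²

where p(A_i B_j) is a cis-haplotype frequency: both alleles must lie on the
same haplotype. Combinations with d = 0 (the allele combination or the
phenotype is monomorphic among included observations) carry no evidence and
are excluded from the maximization; ties are broken by lexicographic
(i, j, k) order. The maximized r equals the largest Pearson correlation
between the (A_i ∧ B_j) indicator and the C_k indicator over haplotype
observations, so a single strongly case-associated allele combination is
detected even when neither SNP shows a marginal signal.

Phase ambiguity: a sample heterozygous at both SNPs whose genotypes are not
both phased has an unknown cis arrangement. By default its haplotypes are
included using the deterministically loaded order and counted in
``n_phase_ambiguous``; ``strict_phase=True`` excludes them from that pair.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np

from ._util import chrom_sort_key
from .errors import InputError
from .io import CASE, HaplotypeMatrix, PhenotypeVector, SNPRecord
from .single import PhenoLike, _status_codes

_COMBOS: Tuple[Tuple[int, int, int], ...] = tuple(
    itertools.product((1, 2), repeat=3)
)


@dataclass
class PairLDResult:
    """Maximized LD between a SNP pair's allele combinations and status.

    ``d_all`` holds the eight D_{ijk} values indexed [i-1, j-1, k-1];
    ``counts`` is the 2×2×2 observation table indexed by allele codes
    [a][b][is_case] (a, b ∈ {0, 1} with 1 = alternate-like A1/B1).
    """

    snp_a: Optional[SNPRecord]
    snp_b: Optional[SNPRecord]
    d_all: Optional[np.ndarray]
    best_combo: Optional[Tuple[int, int, int]]
    r: float
    r2: float
    counts: Optional[np.ndarray]
    n_obs: int
    n_phase_ambiguous: int = 0
    degenerate: bool = False


@dataclass(frozen=True)
class ScanPartition:
    """Half-open anchor-index range [start, end) of one of k_total chunks.

    Expressing the scan as explicit index ranges lets any scheduler split
    the anchor set across machines and merge the chunks afterwards.
    """

    start: int
    end: int
    k_total: int = 1

    def __post_init__(self) -> None:
        if self.start < 0 or not self.start < self.end:
            raise InputError(
                f"invalid partition bounds [{self.start}, {self.end})"
            )
        if self.k_total < 1:
            raise InputError("k_total must be >= 1")


def even_partitions(n_anchors: int, k_total: int) -> List[ScanPartition]:
    """Split [0, n_anchors) into k_total near-equal contiguous partitions."""
    if k_total < 1 or k_total > n_anchors:
        raise InputError("need 1 <= k_total <= number of anchors")
    bounds = np.linspace(0, n_anchors, k_total + 1).astype(int)
    return [
        ScanPartition(int(bounds[i]), int(bounds[i + 1]), k_total)
        for i in range(k_total)
    ]


def _ambiguous_samples(
    alleles_a: np.ndarray,
    alleles_b: np.ndarray,
    phased_a: Optional[np.ndarray],
    phased_b: Optional[np.ndarray],
) -> np.ndarray:
    """Per-sample flag: heterozygous at both SNPs and unphased at either."""
    n_samples = alleles_a.shape[0] // 2
    a0, a1 = alleles_a[0::2], alleles_a[1::2]
    b0, b1 = alleles_b[0::2], alleles_b[1::2]
    het_a = (a0 >= 0) & (a1 >= 0) & (a0 != a1)
    het_b = (b0 >= 0) & (b1 >= 0) & (b0 != b1)
    unphased = np.zeros(n_samples, dtype=bool)
    if phased_a is not None:
        unphased |= ~np.asarray(phased_a, dtype=bool)
    if phased_b is not None:
        unphased |= ~np.asarray(phased_b, dtype=bool)
    return het_a & het_b & unphased


def pair_ld(
    alleles_a: Sequence[int],
    alleles_b: Sequence[int],
    pheno: PhenoLike,
    *,
    phased_a: Optional[Sequence[bool]] = None,
    phased_b: Optional[Sequence[bool]] = None,
    strict_phase: bool = False,
    snp_a: Optional[SNPRecord] = None,
    snp_b: Optional[SNPRecord] = None,
) -> PairLDResult:
    """Compute the maximized 8-combination pair statistic for two SNPs.

    Observations are haplotypes with defined alleles at BOTH SNPs carried by
    a phenotyped sample. If per-sample ``phased_a``/``phased_b`` flags are
    given, doubly-heterozygous unphased samples are counted as
    phase-ambiguous (and dropped when ``strict_phase``). With no usable
    observations, or all eight combinations degenerate, the result is
    flagged degenerate with r = r² = 0.
    """
    a = np.asarray(alleles_a, dtype=np.int8)
    b = np.asarray(alleles_b, dtype=np.int8)
    codes = _status_codes(pheno)
    if a.shape != b.shape or a.shape[0] != 2 * codes.shape[0]:
        raise InputError("allele vectors must both hold 2 haplotypes per sample")

    status_h = np.repeat(codes, 2)
    valid = (a >= 0) & (b >= 0) & (status_h >= 0)
    ambiguous_h = np.repeat(
        _ambiguous_samples(a, b, phased_a, phased_b), 2
    )
    n_ambiguous = int(np.sum(valid & ambiguous_h))
    if strict_phase:
        valid &= ~ambiguous_h
    n = int(valid.sum())
    if n == 0:
        return PairLDResult(
            snp_a, snp_b, None, None, 0.0, 0.0, None, 0, n_ambiguous, True
        )

    cell = (
        a[valid].astype(np.int64) * 4
        + b[valid].astype(np.int64) * 2
        + (status_h[valid] == CASE).astype(np.int64)
    )
    counts = np.bincount(cell, minlength=8).reshape(2, 2, 2)

    # Integer-count forms: for combo (i,j,k) with t haplotypes carrying
    # A_i B_j, m_k in class C_k, D = (n_joint·n − t·m_k)/n² and
    # D/d = (n_joint·n − t·m_k)/sqrt(t(n−t)·m1·m2). Exact under allele and
    # phenotype relabeling and under SNP swap (the 8 combos just permute).
    m_case = int(counts[:, :, 1].sum())
    m_control = n - m_case
    d_all = np.zeros((2, 2, 2), dtype=float)
    best_ratio = -np.inf
    best_combo: Optional[Tuple[int, int, int]] = None
    for i, j, k in _COMBOS:
        ca = 1 if i == 1 else 0  # allele code of A_i (A1 is the alt-like 1)
        cb = 1 if j == 1 else 0
        is_case = 1 if k == 1 else 0
        t = int(counts[ca, cb, :].sum())
        n_joint = int(counts[ca, cb, is_case])
        m_k = m_case if is_case else m_control
        num = n_joint * n - t * m_k
        d_all[i - 1, j - 1, k - 1] = num / (n * n)
        radicand = t * (n - t) * m_case * m_control
        if radicand <= 0:
            continue  # degenerate combination: no evidence either way
        ratio = num / math.sqrt(radicand)
        if ratio > best_ratio:  # first lexicographic (i,j,k) wins ties
            best_ratio = ratio
            best_combo = (i, j, k)
    if best_combo is None:
        return PairLDResult(
            snp_a, snp_b, d_all, None, 0.0, 0.0, counts, n, n_ambiguous, True
        )
    return PairLDResult(
        snp_a,
        snp_b,
        d_all,
        best_combo,
        best_ratio,
        best_ratio * best_ratio,
        counts,
        n,
        n_ambiguous,
        False,
    )


def iter_pairs(
    matrix: HaplotypeMatrix,
    pheno: PhenotypeVector,
    anchor_snps: Sequence[int],
    partition: Optional[ScanPartition] = None,
    strict_phase: bool = False,
) -> Iterator[PairLDResult]:
    """Stream pair results for anchors[start:end] × all other SNPs.

    Anchors are processed in index order within the partition; partners in
    matrix order with self-pairs skipped. The full pair matrix is never
    materialized, keeping memory O(SNPs) however large the scan.
    """
    if list(pheno.samples) != list(matrix.samples):
        raise InputError("phenotype samples do not match genotype samples")
    if partition is None:
        partition = ScanPartition(0, len(anchor_snps), 1)
    if partition.end > len(anchor_snps):
        raise InputError(
            f"partition end {partition.end} exceeds anchor count {len(anchor_snps)}"
        )
    for a_idx in anchor_snps[partition.start : partition.end]:
        if not 0 <= a_idx < matrix.n_snps:
            raise InputError(f"anchor SNP index {a_idx} out of range")
        for b_idx in range(matrix.n_snps):
            if b_idx == a_idx:
                continue
            yield pair_ld(
                matrix.snp_alleles(a_idx),
                matrix.snp_alleles(b_idx),
                pheno,
                phased_a=matrix.snp_phased(a_idx),
                phased_b=matrix.snp_phased(b_idx),
                strict_phase=strict_phase,
                snp_a=matrix.snps[a_idx],
                snp_b=matrix.snps[b_idx],
            )


def multi_scan(
    matrix: HaplotypeMatrix,
    pheno: PhenotypeVector,
    anchor_snps: Sequence[int],
    partition: Optional[ScanPartition] = None,
    min_r2: float = 0.04,
    strict_phase: bool = False,
) -> List[PairLDResult]:
    """Run the anchors × all pair scan, keeping pairs with r² >= min_r2."""
    return [
        res
        for res in iter_pairs(matrix, pheno, anchor_snps, partition, strict_phase)
        if res.r2 >= min_r2
    ]


def _pair_sort_key(res: PairLDResult):
    a, b = res.snp_a, res.snp_b
    return (
        chrom_sort_key(a.chrom),
        a.pos,
        a.id,
        chrom_sort_key(b.chrom),
        b.pos,
        b.id,
    )


def sort_pairs(results: Iterable[PairLDResult]) -> List[PairLDResult]:
    """Canonical (anchor chrom, pos, partner chrom, pos) ordering."""
    return sorted(results, key=_pair_sort_key)


def merge_partitions(
    parts: Sequence[Tuple[ScanPartition, Sequence[PairLDResult]]]
) -> List[PairLDResult]:
    """Merge results from a disjoint partition cover of the anchor range.

    Partitions must tile [0, max end) contiguously with no overlap or gap
    and agree on ``k_total``; the merged list is sorted canonically and is
    identical to a single full-range scan sorted the same way.
    """
    if not parts:
        raise InputError("no partitions to merge")
    ordered = sorted(parts, key=lambda pr: pr[0].start)
    k_totals = {p.k_total for p, _ in ordered}
    if len(k_totals) != 1 or ordered[0][0].k_total != len(ordered):
        raise InputError(
            "partitions disagree on k_total or do not number k_total"
        )
    if ordered[0][0].start != 0:
        raise InputError("partition cover must start at anchor index 0")
    for (prev, _), (nxt, _) in zip(ordered, ordered[1:]):
        if nxt.start < prev.end:
            raise InputError(
                f"overlapping partitions: [{prev.start},{prev.end}) and "
                f"[{nxt.start},{nxt.end})"
            )
        if nxt.start > prev.end:
            raise InputError(
                f"gap in partition cover between {prev.end} and {nxt.start}"
            )
    merged: List[PairLDResult] = []
    for _, results in ordered:
        merged.extend(results)
    return sort_pairs(merged)
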