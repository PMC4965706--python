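"""Synthetic phased case/control cohorts with known planted truth.

The generator emulates the shape of a whole-genome case/control cohort with
unknowns (e.g. 191 cases / 279 controls / 332 unknowns) at desk scale:
phased biallelic SNPs at linkage equilibrium, a logistic liability with
optional per-SNP marginal effects and cis-haplotype pair effects, and exact
requested class counts obtained by seed-deterministic rejection sampling.
Because the pair statistic measures cis co-occurrence, the epistatic effect
is defined on carriage of at least one haplotype bearing the alternate
allele at BOTH planted SNPs.

All outputs (VCF, phenotype TSV, truth JSON) are byte-deterministic for a
fixed config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit

from ._util import atomic_write_text
from .errors import InputError
from .io import (
    CASE,
    CONTROL,
    UNKNOWN,
    HaplotypeMatrix,
    PhenotypeVector,
    SNPRecord,
    write_phenotypes,
    write_vcf,
)

_BATCH = 512
_MAX_DRAW_FACTOR = 2000  # rejection-sampling budget per requested sample


@dataclass(frozen=True)
class SimConfig:
    """Cohort recipe: sample counts, SNP panel, and planted effects.

    ``planted_single`` entries are (snp_index, beta) log-odds per copy of
    the alternate allele; ``planted_pairs`` entries are
    (snp_index_a, snp_index_b, beta) log-odds for carrying >= 1 haplotype
    with the alternate allele at both SNPs in cis. Allele frequencies refer
    to the alternate (A1) allele and are drawn uniformly from ``maf_range``.
    """

    n_cases: int
    n_controls: int
    n_unknown: int = 0
    n_snps: int = 100
    maf_range: Tuple[float, float] = (0.05, 0.45)
    planted_single: Tuple[Tuple[int, float], ...] = ()
    planted_pairs: Tuple[Tuple[int, int, float], ...] = ()
    baseline_logit: float = -1.0
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.maf_range
        if not 0.0 < low <= high < 0.5:
            raise InputError(f"maf_range must satisfy 0 < low <= high < 0.5")
        if min(self.n_cases, self.n_controls, self.n_unknown) < 0:
            raise InputError("sample counts must be non-negative")
        if self.n_snps < 1:
            raise InputError("n_snps must be >= 1")
        planted = [i for i, _ in self.planted_single]
        for a, b, _ in self.planted_pairs:
            planted.extend((a, b))
        if len(planted) != len(set(planted)):
            raise InputError("planted SNP indices must be distinct")
        if planted and (min(planted) < 0 or max(planted) >= self.n_snps):
            raise InputError("planted SNP indices must lie in [0, n_snps)")


class SimulatedCohort(NamedTuple):
    matrix: HaplotypeMatrix
    pheno: PhenotypeVector
    truth: Dict


class CohortFiles(NamedTuple):
    vcf: str
    phenotypes: str
    truth: str


def _case_probability(haps: np.ndarray, config: SimConfig) -> np.ndarray:
    """P(case) per individual from the logistic liability. ``haps`` is
    (n_individuals, n_snps, 2) boolean, True = alternate allele."""
    logit = np.full(haps.shape[0], config.baseline_logit, dtype=float)
    for idx, beta in config.planted_single:
        logit += beta * haps[:, idx, :].sum(axis=-1)
    for a, b, beta in config.planted_pairs:
        cis = (haps[:, a, :] & haps[:, b, :]).any(axis=-1)
        logit += beta * cis
    return expit(logit)


def simulate_matrix(config: SimConfig) -> SimulatedCohort:
    """Generate the cohort in memory.

    Individuals are drawn in fixed-size batches; each is assigned case with
    its liability probability and accepted while its class quota remains
    open, so the exact requested case/control counts are met. Unknown
    samples are genotype-only draws appended after the phenotyped ones.
    Exceeding the rejection budget (pathological betas) raises InputError.
    """
    rng = np.random.default_rng(config.seed)
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], config.n_snps)

    accepted: List[np.ndarray] = []
    statuses: List[int] = []
    need_case, need_control = config.n_cases, config.n_controls
    drawn = 0
    budget = _MAX_DRAW_FACTOR * (config.n_cases + config.n_controls + 1)
    while need_case > 0 or need_control > 0:
        if drawn > budget:
            raise InputError(
                "case/control quotas unattainable under the configured "
                "liability model (rejection budget exhausted)"
            )
        haps = rng.random((_BATCH, config.n_snps, 2)) < freqs[None, :, None]
        p_case = _case_probability(haps, config)
        is_case = rng.random(_BATCH) < p_case
        drawn += _BATCH
        for row in range(_BATCH):
            if is_case[row] and need_case > 0:
                accepted.append(haps[row])
                statuses.append(CASE)
                need_case -= 1
            elif not is_case[row] and need_control > 0:
                accepted.append(haps[row])
                statuses.append(CONTROL)
                need_control -= 1
            if need_case == 0 and need_control == 0:
                break
    for _ in range(config.n_unknown):
        accepted.append(rng.random((config.n_snps, 2)) < freqs[:, None])
        statuses.append(UNKNOWN)

    n_ind = len(accepted)
    alleles = np.empty((config.n_snps, 2 * n_ind), dtype=np.int8)
    for j, haps_j in enumerate(accepted):
        alleles[:, 2 * j] = haps_j[:, 0]
        alleles[:, 2 * j + 1] = haps_j[:, 1]
    samples = [f"s{j + 1:04d}" for j in range(n_ind)]
    snps = [
        SNPRecord(
            chrom="1",
            pos=(i + 1) * 100,
            id=f"snp{i + 1:05d}",
            ref="A",
            alt="G",
        )
        for i in range(config.n_snps)
    ]
    matrix = HaplotypeMatrix(
        snps=snps,
        samples=samples,
        alleles=alleles,
        phased=np.ones((config.n_snps, n_ind), dtype=bool),
    )
    pheno = PhenotypeVector(samples, np.array(statuses, dtype=np.int8))
    truth = {
        "seed": config.seed,
        "n_cases": config.n_cases,
        "n_controls": config.n_controls,
        "n_unknown": config.n_unknown,
        "n_snps": config.n_snps,
        "baseline_logit": config.baseline_logit,
        "maf_range": list(config.maf_range),
        "allele_frequencies": [float(f) for f in freqs],
        "planted_single": [[int(i), float(b)] for i, b in config.planted_single],
        "planted_pairs": [
            [int(a), int(b), float(beta)] for a, b, beta in config.planted_pairs
        ],
    }
    return SimulatedCohort(matrix, pheno, truth)


def simulate_cohort(config: SimConfig, out_prefix: str) -> CohortFiles:
    """Generate the cohort and write {prefix}.vcf, {prefix}.pheno.tsv and
    {prefix}.truth.json; returns the three paths."""
    cohort = simulate_matrix(config)
    vcf_path = f"{out_prefix}.vcf"
    pheno_path = f"{out_prefix}.pheno.tsv"
    truth_path = f"{out_prefix}.truth.json"
    write_vcf(cohort.matrix, vcf_path, source="ldgwas-simulate")
    write_phenotypes(cohort.pheno, pheno_path)
    atomic_write_text(truth_path, json.dumps(cohort.truth, indent=2) + "\n")
    return CohortFiles(vcf_path, pheno_path, truth_path)


def worked_example_fixture() -> Tuple[HaplotypeMatrix, PhenotypeVector]:
    """The 8-haplotype, 2-SNP, 4-sample toy used throughout the docs.

    Two case samples with haplotypes (A,B) = (1,1),(1,1) and (1,0),(0,1);
    two control samples with (1,0),(0,1) and (0,0),(0,0). Hand-checkable:
    the single-SNP statistic on SNP A gives D = 0.125, r = 0.5, r² = 0.25;
    the pair statistic gives r² = 1/3 at combination (A1, B1, case).
    """
    snps = [
        SNPRecord(chrom="1", pos=100, id="snpA", ref="A", alt="G"),
        SNPRecord(chrom="1", pos=200, id="snpB", ref="C", alt="T"),
    ]
    samples = ["s1", "s2", "s3", "s4"]
    # haplotype columns: s1h1 s1h2 s2h1 s2h2 s3h1 s3h2 s4h1 s4h2
    alleles = np.array(
        [
            [1, 1, 1, 0, 1, 0, 0, 0],  # SNP A
            [1, 1, 0, 1, 0, 1, 0, 0],  # SNP B
        ],
        dtype=np.int8,
    )
    phased = np.ones((2, 4), dtype=bool)
    matrix = HaplotypeMatrix(snps, samples, alleles, phased)
    pheno = PhenotypeVector(
        samples, np.array([CASE, CASE, CONTROL, CONTROL], dtype=np.int8)
    )
    return matrix, pheno


def write_worked_example(out_prefix: str) -> CohortFiles:
    """Write the toy fixture as {prefix}.vcf + {prefix}.pheno.tsv."""
    matrix, pheno = worked_example_fixture()
    vcf_path = f"{out_prefix}.vcf"
    pheno_path = f"{out_prefix}.pheno.tsv"
    truth_path = f"{out_prefix}.truth.json"
    write_vcf(matrix, vcf_path, source="ldgwas-fixture")
    write_phenotypes(pheno, pheno_path)
    atomic_write_text(
        truth_path,
        json.dumps(
            {"single_snpA": {"D": 0.125, "r": 0.5, "r2": 0.25}, "pair_r2": 1 / 3},
            indent=2,
        )
        + "\n",
    )
    return CohortFiles(vcf_path, pheno_path, truth_path)
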