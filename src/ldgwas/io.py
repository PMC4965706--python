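"""Genotype, phenotype and gene-region input/output.

Genotypes are held at haplotype resolution: every diploid sample contributes
exactly two haplotype columns, coded ``1`` for the alternate-like allele
(the event allele, A1/B1), ``0`` for the reference-like allele (A2/B2) and
``-1`` for missing. Case/control status is the third "locus": the scan
statistics correlate allele indicators with the case indicator over these
haplotype observations.

Conventions
-----------
* VCF positions are 1-based throughout; BED regions are 0-based half-open on
  input only. A SNP at 1-based position ``pos`` lies in region ``[start, end)``
  iff ``start < pos <= end``.
* Unphased genotypes are loaded with the reference allele first (a
  deterministic order) and flagged unphased; downstream pair statistics
  decide how to treat phase-ambiguous samples.
* Half-calls (e.g. ``0/.``) are loaded as fully missing at that site.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
from cyvcf2 import VCF

from .errors import InputError, VCFParseError

# Per-sample status codes used everywhere in the package.
CASE: int = 1
CONTROL: int = 0
UNKNOWN: int = -1
MISSING: int = -1  # haplotype allele code for a missing call

_STATUS_TOKENS: Dict[str, int] = {
    "1": CASE,
    "case": CASE,
    "0": CONTROL,
    "control": CONTROL,
    "na": UNKNOWN,
    "unknown": UNKNOWN,
    "-9": UNKNOWN,
}

_STATUS_NAMES = {CASE: "case", CONTROL: "control", UNKNOWN: "unknown"}


@dataclass(frozen=True)
class SNPRecord:
    """One biallelic variant site."""

    chrom: str
    pos: int  # 1-based, VCF convention
    id: str = "."
    ref: str = "N"
    alt: str = "N"
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError(f"SNP position must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class GeneRegion:
    """A gene interval in BED convention: 0-based start, exclusive end."""

    chrom: str
    start: int
    end: int
    gene: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise InputError(
                f"gene region must satisfy start < end, got [{self.start}, {self.end})"
            )

    def contains(self, pos: int) -> bool:
        """True iff the 1-based position falls inside this region."""
        return self.start < pos <= self.end


@dataclass
class PhenotypeVector:
    """Per-sample case/control/unknown status aligned to a sample list.

    ``codes`` holds one int8 per sample: 1 case, 0 control, -1 unknown.
    Unknown-status samples are excluded from every statistic.
    """

    samples: List[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.samples),):
            raise InputError("phenotype codes must align 1:1 with samples")
        bad = set(np.unique(self.codes)) - {CASE, CONTROL, UNKNOWN}
        if bad:
            raise InputError(f"invalid status codes: {sorted(bad)}")

    @classmethod
    def from_mapping(
        cls, status: Mapping[str, int], sample_ids: Sequence[str]
    ) -> "PhenotypeVector":
        codes = np.array(
            [status.get(s, UNKNOWN) for s in sample_ids], dtype=np.int8
        )
        return cls(list(sample_ids), codes)

    @property
    def n_case(self) -> int:
        return int(np.sum(self.codes == CASE))

    @property
    def n_control(self) -> int:
        return int(np.sum(self.codes == CONTROL))

    @property
    def n_unknown(self) -> int:
        return int(np.sum(self.codes == UNKNOWN))

    def status_name(self, sample_index: int) -> str:
        return _STATUS_NAMES[int(self.codes[sample_index])]


@dataclass
class HaplotypeMatrix:
    """Haplotype allele codes for many SNPs across samples.

    ``alleles`` has shape ``(n_snps, 2 * n_samples)``; sample ``j`` owns
    columns ``2j`` and ``2j + 1``. ``phased`` has shape
    ``(n_snps, n_samples)`` and records whether the GT was phased in the
    source file.
    """

    snps: List[SNPRecord]
    samples: List[str]
    alleles: np.ndarray
    phased: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.phased = np.asarray(self.phased, dtype=bool)
        n_snps, n_hap = self.alleles.shape if self.alleles.ndim == 2 else (0, 0)
        if self.alleles.ndim != 2 or n_hap != 2 * len(self.samples):
            raise InputError(
                "allele matrix must have exactly 2 haplotype columns per sample"
            )
        if n_snps != len(self.snps):
            raise InputError("allele matrix rows must align with SNP records")
        if self.phased.shape != (n_snps, len(self.samples)):
            raise InputError("phased flags must be (n_snps, n_samples)")
        bad = set(np.unique(self.alleles)) - {0, 1, MISSING} if n_snps else set()
        if bad:
            raise InputError(f"allele codes must be 0/1/missing, got {sorted(bad)}")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def snp_alleles(self, i: int) -> np.ndarray:
        """Haplotype allele codes for SNP ``i`` (length 2 * n_samples)."""
        return self.alleles[i]

    def snp_phased(self, i: int) -> np.ndarray:
        """Per-sample phased flags for SNP ``i``."""
        return self.phased[i]


def _is_snp_allele(a: str) -> bool:
    return len(a) == 1 and a.upper() in "ACGT"


def load_vcf(
    path: str,
    regions: Optional[Sequence[GeneRegion]] = None,
    biallelic_only: bool = True,
) -> HaplotypeMatrix:
    """Read a VCF 4.x file with per-sample GT into a :class:`HaplotypeMatrix`.

    Parameters
    ----------
    path:
        VCF path (plain or bgzipped).
    regions:
        If given, only variants whose position falls inside at least one
        region are loaded.
    biallelic_only:
        Skip multi-allelic sites and non-SNP variants. When False,
        multi-allelic sites are kept with every alternate allele coded 1.

    Missing genotypes (``./.``) and half-calls yield missing codes for both
    haplotypes; unphased heterozygotes are stored reference-allele first and
    flagged unphased.
    """
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise VCFParseError(f"cannot open VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise InputError(f"VCF {path!r} contains zero samples")

    snps: List[SNPRecord] = []
    allele_rows: List[np.ndarray] = []
    phased_rows: List[np.ndarray] = []
    record_index = 0
    try:
        for v in vcf:
            record_index += 1
            alts = [a for a in v.ALT if a != "<NON_REF>"]
            if biallelic_only:
                if len(alts) != 1:
                    continue
                if not (_is_snp_allele(v.REF) and _is_snp_allele(alts[0])):
                    continue
            elif not alts:
                continue
            if regions is not None and not any(
                r.chrom == v.CHROM and r.contains(v.POS) for r in regions
            ):
                continue
            row = np.empty(2 * len(samples), dtype=np.int8)
            phased_row = np.empty(len(samples), dtype=bool)
            for j, gt in enumerate(v.genotypes):
                *calls, is_phased = gt
                if len(calls) != 2 or calls[0] < 0 or calls[1] < 0:
                    # missing call, half-call, or non-diploid record
                    a0 = a1 = MISSING
                    is_phased = bool(is_phased) and len(calls) == 2
                else:
                    a0 = 1 if calls[0] >= 1 else 0
                    a1 = 1 if calls[1] >= 1 else 0
                    if not is_phased and a0 > a1:
                        a0, a1 = a1, a0  # deterministic REF-first order
                row[2 * j] = a0
                row[2 * j + 1] = a1
                phased_row[j] = bool(is_phased)
            snps.append(
                SNPRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    id=v.ID or ".",
                    ref=v.REF,
                    alt=alts[0] if alts else ".",
                )
            )
            allele_rows.append(row)
            phased_rows.append(phased_row)
    except VCFParseError:
        raise
    except Exception as exc:
        raise VCFParseError(
            f"malformed VCF {path!r} at variant record {record_index + 1}: {exc}"
        ) from exc

    n = len(snps)
    alleles = (
        np.vstack(allele_rows)
        if n
        else np.empty((0, 2 * len(samples)), dtype=np.int8)
    )
    phased = (
        np.vstack(phased_rows) if n else np.empty((0, len(samples)), dtype=bool)
    )
    return HaplotypeMatrix(snps=snps, samples=samples, alleles=alleles, phased=phased)


def write_vcf(matrix: HaplotypeMatrix, path: str, source: str = "ldgwas") -> None:
    """Write the matrix as a minimal VCF 4.2 text file.

    Phased samples are written ``a|b``, unphased ``a/b``, missing ``./.``.
    Round-trips exactly through :func:`load_vcf` for phased data.
    """
    lines = ["##fileformat=VCFv4.2", f"##source={source}"]
    for chrom in dict.fromkeys(s.chrom for s in matrix.snps):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples)
    )
    for i, snp in enumerate(matrix.snps):
        row = matrix.alleles[i]
        phased = matrix.phased[i]
        gts = []
        for j in range(matrix.n_samples):
            a0, a1 = row[2 * j], row[2 * j + 1]
            sep = "|" if phased[j] else "/"
            if a0 == MISSING or a1 == MISSING:
                gts.append(f".{sep}.")
            else:
                gts.append(f"{a0}{sep}{a1}")
        lines.append(
            f"{snp.chrom}\t{snp.pos}\t{snp.id}\t{snp.ref}\t{snp.alt}\t.\tPASS\t.\tGT\t"
            + "\t".join(gts)
        )
    from ._util import atomic_write_text

    atomic_write_text(path, "\n".join(lines) + "\n")


def load_phenotypes(path: str, sample_ids: Sequence[str]) -> PhenotypeVector:
    """Read a TSV of ``sample_id<TAB>status`` into a status vector aligned to
    ``sample_ids``.

    Status tokens: ``1``/``case`` are cases, ``0``/``control`` controls,
    ``NA``/``unknown``/``-9`` unknown. A header line is optional. Samples
    absent from the file default to unknown.
    """
    status: Dict[str, int] = {}
    known = set(sample_ids)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise InputError(
                    f"{path}:{lineno}: expected sample_id<TAB>status, got {line!r}"
                )
            sid, token = fields[0], fields[1]
            code = _STATUS_TOKENS.get(token.lower())
            if code is None:
                # tolerate a single header line (its id is not a sample)
                if lineno == 1 and sid not in known:
                    continue
                raise InputError(
                    f"{path}:{lineno}: unrecognized status token {token!r} "
                    f"(expected one of {sorted(_STATUS_TOKENS)})"
                )
            status[sid] = code
    return PhenotypeVector.from_mapping(status, sample_ids)


def write_phenotypes(pheno: PhenotypeVector, path: str) -> None:
    """Write the phenotype vector as sample_id<TAB>status TSV (with header)."""
    from ._util import atomic_write_text

    lines = ["sample_id\tstatus"]
    for i, sid in enumerate(pheno.samples):
        lines.append(f"{sid}\t{pheno.status_name(i)}")
    atomic_write_text(path, "\n".join(lines) + "\n")


def load_gene_regions(path: str) -> List[GeneRegion]:
    """Read gene regions from a BED file (chrom, start, end, gene name)."""
    regions: List[GeneRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise InputError(
                    f"{path}:{lineno}: need chrom, start, end, gene columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: non-integer coordinates") from exc
            regions.append(GeneRegion(fields[0], start, end, fields[3]))
    return regions


def annotate_genes(
    matrix: HaplotypeMatrix, regions: Sequence[GeneRegion]
) -> HaplotypeMatrix:
    """Assign gene symbols to SNPs falling inside the supplied regions.

    Regions are sorted by (chrom, start) first, so the result does not depend
    on input order; a SNP covered by several overlapping regions takes the
    gene of the region with the smallest start. SNPs outside every region
    keep ``gene=None``.
    """
    by_chrom: Dict[str, List[GeneRegion]] = {}
    for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end, r.gene)):
        by_chrom.setdefault(r.chrom, []).append(r)

    new_snps: List[SNPRecord] = []
    for snp in matrix.snps:
        gene = None
        for r in by_chrom.get(snp.chrom, ()):
            if r.start >= snp.pos:  # sorted by start; nothing further can match
                break
            if r.contains(snp.pos):
                gene = r.gene
                break
        new_snps.append(dataclasses.replace(snp, gene=gene))
    return HaplotypeMatrix(
        snps=new_snps,
        samples=matrix.samples,
        alleles=matrix.alleles,
        phased=matrix.phased,
    )


def genic_snp_indices(matrix: HaplotypeMatrix) -> List[int]:
    """Indices of SNPs carrying a gene annotation."""
    return [i for i, s in enumerate(matrix.snps) if s.gene is not None]


def snps_in_regions(
    matrix: HaplotypeMatrix, regions: Sequence[GeneRegion]
) -> List[int]:
    """Indices of SNPs whose position falls in any of the regions."""
    return [
        i
        for i, s in enumerate(matrix.snps)
        if any(r.chrom == s.chrom and r.contains(s.pos) for r in regions)
    ]
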