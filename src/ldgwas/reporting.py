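"""Result tables and plot data.

The canonical artifacts are deterministic TSV tables: the per-SNP r² table
(Manhattan-plot data), the pair-scan table, the gene-pair summary (one row
per unordered gene pair, keeping the best SNP pair and the count of
significant pairs), and the index-based pair-matrix table behind the banded
significant-pair scatter. Plot rendering is a thin optional helper; the
tables are the contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from ._util import atomic_write_text, chrom_sort_key
from .io import SNPRecord
from .pairs import PairLDResult, sort_pairs
from .single import SingleLDResult

SINGLE_COLUMNS = [
    "chrom",
    "pos",
    "id",
    "gene",
    "D",
    "r",
    "r2",
    "n_obs",
    "degenerate_flag",
]

PAIR_COLUMNS = [
    "anchor_chrom",
    "anchor_pos",
    "anchor_id",
    "anchor_gene",
    "partner_chrom",
    "partner_pos",
    "partner_id",
    "partner_gene",
    "best_i",
    "best_j",
    "best_k",
    "D_best",
    "r",
    "r2",
    "n_obs",
    "n_phase_ambiguous",
]

GENE_PAIR_COLUMNS = [
    "gene_a",
    "gene_b",
    "anchor_chrom",
    "anchor_pos",
    "anchor_id",
    "partner_chrom",
    "partner_pos",
    "partner_id",
    "r2",
    "n_significant",
]

# Bucket width for the positional pseudo-gene label of un-annotated SNPs.
PSEUDO_GENE_BUCKET = 1_000_000


def singles_to_frame(results: Sequence[SingleLDResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        snp = res.snp
        rows.append(
            {
                "chrom": snp.chrom if snp else "",
                "pos": snp.pos if snp else 0,
                "id": snp.id if snp else ".",
                "gene": (snp.gene or "") if snp else "",
                "D": res.D,
                "r": res.r,
                "r2": res.r2,
                "n_obs": res.n_obs,
                "degenerate_flag": int(res.degenerate),
            }
        )
    return pd.DataFrame(rows, columns=SINGLE_COLUMNS)


def pairs_to_frame(results: Sequence[PairLDResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        a, b = res.snp_a, res.snp_b
        i, j, k = res.best_combo if res.best_combo else (0, 0, 0)
        d_best = (
            res.d_all[i - 1, j - 1, k - 1]
            if res.best_combo is not None and res.d_all is not None
            else 0.0
        )
        rows.append(
            {
                "anchor_chrom": a.chrom if a else "",
                "anchor_pos": a.pos if a else 0,
                "anchor_id": a.id if a else ".",
                "anchor_gene": (a.gene or "") if a else "",
                "partner_chrom": b.chrom if b else "",
                "partner_pos": b.pos if b else 0,
                "partner_id": b.id if b else ".",
                "partner_gene": (b.gene or "") if b else "",
                "best_i": i,
                "best_j": j,
                "best_k": k,
                "D_best": d_best,
                "r": res.r,
                "r2": res.r2,
                "n_obs": res.n_obs,
                "n_phase_ambiguous": res.n_phase_ambiguous,
            }
        )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def manhattan_table(results: Sequence[SingleLDResult]) -> pd.DataFrame:
    """(chrom, pos, r2) rows sorted by genomic position, ready to plot."""
    rows = [
        {"chrom": res.snp.chrom, "pos": res.snp.pos, "r2": res.r2}
        for res in results
        if res.snp is not None
    ]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "r2"])
    if len(df):
        df = df.sort_values(
            by=["chrom", "pos"],
            key=lambda col: (
                col.map(chrom_sort_key) if col.name == "chrom" else col
            ),
            kind="mergesort",
        ).reset_index(drop=True)
    return df


def _gene_label(snp: SNPRecord) -> str:
    """Gene symbol, or a positional chrom:bucket pseudo-gene for SNPs
    outside every supplied gene region."""
    if snp.gene:
        return snp.gene
    return f"{snp.chrom}:{snp.pos // PSEUDO_GENE_BUCKET}"


@dataclass
class GenePairSummary:
    """Best SNP pair and significant-pair count for one unordered gene pair."""

    gene_a: str
    gene_b: str
    best_pair: PairLDResult
    n_significant: int


def summarize_gene_pairs(
    pairs: Sequence[PairLDResult],
) -> List[GenePairSummary]:
    """Collapse significant SNP pairs to one row per unordered gene pair.

    Each row keeps the SNP pair with the highest r² for that gene pair and
    the count of significant SNP pairs between the two genes. Rows are
    sorted by best r² descending, ties by (gene_a, gene_b).
    """
    groups: Dict[Tuple[str, str], List[PairLDResult]] = {}
    for res in pairs:
        ga, gb = _gene_label(res.snp_a), _gene_label(res.snp_b)
        key = (ga, gb) if ga <= gb else (gb, ga)
        groups.setdefault(key, []).append(res)
    summaries = []
    for (ga, gb), members in groups.items():
        best = min(
            members,
            key=lambda m: (
                -m.r2,
                chrom_sort_key(m.snp_a.chrom),
                m.snp_a.pos,
                m.snp_a.id,
                chrom_sort_key(m.snp_b.chrom),
                m.snp_b.pos,
                m.snp_b.id,
            ),
        )
        summaries.append(GenePairSummary(ga, gb, best, len(members)))
    summaries.sort(key=lambda s: (-s.best_pair.r2, s.gene_a, s.gene_b))
    return summaries


def gene_pairs_to_frame(summaries: Sequence[GenePairSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        a, b = s.best_pair.snp_a, s.best_pair.snp_b
        rows.append(
            {
                "gene_a": s.gene_a,
                "gene_b": s.gene_b,
                "anchor_chrom": a.chrom,
                "anchor_pos": a.pos,
                "anchor_id": a.id,
                "partner_chrom": b.chrom,
                "partner_pos": b.pos,
                "partner_id": b.id,
                "r2": s.best_pair.r2,
                "n_significant": s.n_significant,
            }
        )
    return pd.DataFrame(rows, columns=GENE_PAIR_COLUMNS)


def pair_matrix_table(
    pairs: Sequence[PairLDResult], snps: Sequence[SNPRecord]
) -> pd.DataFrame:
    """Index-based pair table for the significant-pair scatter.

    SNPs are ranked 0-based by (chrom, pos, id) over the analyzed SNP set —
    indices preserve relative genomic order but are compact ranks, not
    positions — and each significant pair is emitted as
    (anchor_snp_index, partner_snp_index, r2, genes). Shared anchors show up
    as repeated anchor indices, the vertical bands of the scatter.
    """
    order = sorted(
        range(len(snps)),
        key=lambda i: (chrom_sort_key(snps[i].chrom), snps[i].pos, snps[i].id),
    )
    rank = {
        (snps[i].chrom, snps[i].pos, snps[i].id): r for r, i in enumerate(order)
    }
    rows = []
    for res in pairs:
        a, b = res.snp_a, res.snp_b
        ka, kb = (a.chrom, a.pos, a.id), (b.chrom, b.pos, b.id)
        if ka not in rank or kb not in rank:
            continue  # pair involves a SNP outside the analyzed set
        rows.append(
            {
                "anchor_snp_index": rank[ka],
                "partner_snp_index": rank[kb],
                "r2": res.r2,
                "anchor_gene": a.gene or "",
                "partner_gene": b.gene or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "anchor_snp_index",
            "partner_snp_index",
            "r2",
            "anchor_gene",
            "partner_gene",
        ],
    )


def write_table(df: pd.DataFrame, path: str) -> None:
    """Write a TSV with header, atomically (via a .partial temp file)."""
    atomic_write_text(path, df.to_csv(sep="\t", index=False))


def plot_manhattan(df: pd.DataFrame, path: str) -> None:
    """Render the per-SNP r² table as a Manhattan-style scatter (r² on y)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    chroms = list(dict.fromkeys(df["chrom"])) if len(df) else []
    offset, ticks = 0, []
    for ci, chrom in enumerate(chroms):
        sub = df[df["chrom"] == chrom]
        x = offset + (sub["pos"] - sub["pos"].min())
        ax.scatter(x, sub["r2"], s=4, color=f"C{ci % 10}")
        ticks.append((offset + x.max()) / 2 if len(sub) else offset)
        offset = (x.max() if len(sub) else offset) + 1
    ax.set_xticks(ticks)
    ax.set_xticklabels(chroms, fontsize=7)
    ax.set_ylabel("r²")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pair_matrix(
    df: pd.DataFrame, path: str, label_min_pairs: int = 44
) -> None:
    """Scatter of significant pairs by SNP index; genes with at least
    ``label_min_pairs`` pairings are labeled on the partner axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(df["anchor_snp_index"], df["partner_snp_index"], s=5)
    if len(df):
        counts = df.groupby("partner_gene").size()
        for gene, n in counts.items():
            if gene and n >= label_min_pairs:
                y = df.loc[df["partner_gene"] == gene, "partner_snp_index"].median()
                ax.annotate(gene, (df["anchor_snp_index"].max(), y), fontsize=7)
    ax.set_xlabel("anchor SNP index")
    ax.set_ylabel("partner SNP index")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
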