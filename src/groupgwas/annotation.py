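"""SNP-to-gene assignment via extended gene regions and per-group SNP indexes.

A SNP belongs to a gene when its position falls inside the gene interval
extended by an upstream window at the 5' end and a downstream window at the
3' end (strand-aware; defaults 2 kb / 500 bp).  SNPs inside several extended
regions are assigned to every one of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genotype_io import GeneGroup, GeneRegion, SnpRecord

logger = logging.getLogger(__name__)

UPSTREAM_BP = 2000
DOWNSTREAM_BP = 500


@dataclass(frozen=True)
class SnpGeneAssignment:
    snp_id: str
    gene_id: str


@dataclass
class GroupSnpIndex:
    """SNPs covered by a gene group: deduplicated union over member genes."""

    group_name: str
    snp_ids: list[str]
    n_genes_covered: int


def extend_gene_region(
    gene: GeneRegion,
    upstream_bp: int = UPSTREAM_BP,
    downstream_bp: int = DOWNSTREAM_BP,
) -> tuple[int, int]:
    """Extended interval (1-based inclusive) around a gene.

    The upstream window is added to the 5' end and the downstream window to
    the 3' end, so the extension mirrors for minus-strand genes.  Genes with
    unknown strand are treated as plus-strand.  The lower bound is clipped
    at position 1.
    """
    if gene.strand == "-":
        lo, hi = gene.start - downstream_bp, gene.end + upstream_bp
    else:
        lo, hi = gene.start - upstream_bp, gene.end + downstream_bp
    return max(lo, 1), hi


def map_snps_to_genes(
    snps: list[SnpRecord],
    genes: list[GeneRegion],
    upstream_bp: int = UPSTREAM_BP,
    downstream_bp: int = DOWNSTREAM_BP,
) -> list[SnpGeneAssignment]:
    """Assign every SNP to every gene whose extended region contains it.

    Boundaries are inclusive.  SNPs on chromosomes absent from the
    annotation are left unassigned.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gene in genes:
        lo, hi = extend_gene_region(gene, upstream_bp, downstream_bp)
        by_chrom.setdefault(gene.chrom, []).append((lo, hi, gene.gene_id))

    # sort intervals by start; binary-search candidate windows per SNP
    sorted_chrom: dict[str, tuple[np.ndarray, list[tuple[int, int, str]]]] = {}
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        starts = np.array([iv[0] for iv in ivals])
        sorted_chrom[chrom] = (starts, ivals)

    assignments: list[SnpGeneAssignment] = []
    for snp in snps:
        entry = sorted_chrom.get(snp.chrom)
        if entry is None:
            continue
        starts, ivals = entry
        hi_idx = int(np.searchsorted(starts, snp.pos, side="right"))
        for lo, hi, gene_id in ivals[:hi_idx]:
            if lo <= snp.pos <= hi:
                assignments.append(SnpGeneAssignment(snp.snp_id, gene_id))
    return assignments


def build_group_index(
    assignments: list[SnpGeneAssignment],
    groups: list[GeneGroup],
) -> list[GroupSnpIndex]:
    """Per-group union of SNPs over member genes.

    Each SNP is counted once per group even when assigned to several member
    genes; ``n_genes_covered`` counts member genes with at least one SNP.
    Groups with zero covered genes produce an empty index with a warning.
    """
    snps_by_gene: dict[str, list[str]] = {}
    for a in assignments:
        snps_by_gene.setdefault(a.gene_id, []).append(a.snp_id)

    indexes = []
    for group in groups:
        seen: set[str] = set()
        snp_ids: list[str] = []
        covered = 0
        for gene_id in sorted(group.gene_ids):
            gene_snps = snps_by_gene.get(gene_id)
            if not gene_snps:
                continue
            covered += 1
            for s in gene_snps:
                if s not in seen:
                    seen.add(s)
                    snp_ids.append(s)
        if covered == 0:
            logger.warning("gene group %r has no genes with SNPs", group.group_name)
        indexes.append(GroupSnpIndex(group.group_name, snp_ids, covered))
    return indexes


def write_assignments(assignments: list[SnpGeneAssignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("SNP\tGENE\n")
        for a in assignments:
            fh.write(f"{a.snp_id}\t{a.gene_id}\n")


def write_group_index_summary(indexes: list[GroupSnpIndex], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("GROUP\tN_GENES\tN_SNPS\n")
        for ix in indexes:
            fh.write(f"{ix.group_name}\t{ix.n_genes_covered}\t{len(ix.snp_ids)}\n")
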