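"""Pairwise-r2 LD, tagging and per-gene array coverage accounting.

An untyped common SNP counts as tagged when its squared dosage correlation
with at least one genotyped SNP in the same gene region reaches the r2
threshold.  The gene coverage rate is (typed + tagged) / common, where
"common" means minor allele frequency strictly above the floor; typed SNPs
are not restricted to common ones, so the rate may exceed 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .genotype_io import GenotypeMatrix

DEFAULT_MAF_FLOOR = 0.05
DEFAULT_R2_MIN = 0.80


@dataclass
class CoverageRecord:
    gene_id: str
    n_total: int
    n_common: int
    n_typed: int
    n_tagged: int
    coverage_rate: float | None  # None when no common SNPs exist


def genotype_r2(d1: np.ndarray, d2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (composite LD).

    Pairwise-complete deletion; needs >= 3 complete pairs and both vectors
    non-constant on the complete set, otherwise returns nan (treated as
    untagged by the caller).
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    keep = ~np.isnan(d1) & ~np.isnan(d2)
    x, y = d1[keep], d2[keep]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(min(r * r, 1.0))


def minor_allele_freq(dosage: np.ndarray) -> float:
    """MAF from non-missing dosages; nan for all-missing."""
    d = np.asarray(dosage, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        return float("nan")
    f = d.mean() / 2.0
    return float(min(f, 1.0 - f))


def coverage_rate(n_typed: int, n_tagged: int, n_common: int) -> float | None:
    """(typed + tagged) / common; None (rendered "-") when common = 0."""
    if min(n_typed, n_tagged, n_common) < 0:
        raise ValueError("counts must be non-negative")
    if n_common == 0:
        return None
    return (n_typed + n_tagged) / n_common


def compute_tagging(
    reference: GenotypeMatrix,
    typed_ids: set[str],
    gene_id: str = "gene",
    maf_floor: float = DEFAULT_MAF_FLOOR,
    r2_min: float = DEFAULT_R2_MIN,
) -> CoverageRecord:
    """Coverage record for one gene region of a reference panel.

    ``reference`` holds every known SNP in the (extended) gene region;
    ``typed_ids`` names those genotyped on the array.  A common untyped SNP
    is tagged when r2 >= ``r2_min`` with >= 1 typed SNP in the region.
    """
    unknown = typed_ids - set(reference.snp_ids)
    if unknown:
        raise ValueError(f"typed ids absent from reference panel: {sorted(unknown)[:5]}")
    n_total = reference.n_snps
    if n_total == 0:
        return CoverageRecord(gene_id, 0, 0, 0, 0, None)

    mafs = np.array([minor_allele_freq(reference.dosage[:, j]) for j in range(n_total)])
    common = mafs > maf_floor
    typed = np.array([s in typed_ids for s in reference.snp_ids])
    typed_cols = np.flatnonzero(typed)

    n_tagged = 0
    for j in np.flatnonzero(common & ~typed):
        for k in typed_cols:
            r2 = genotype_r2(reference.dosage[:, j], reference.dosage[:, k])
            if not np.isnan(r2) and r2 >= r2_min:
                n_tagged += 1
                break
    n_common = int(common.sum())
    n_typed = int(typed.sum())
    return CoverageRecord(gene_id, n_total, n_common, n_typed, n_tagged, coverage_rate(n_typed, n_tagged, n_common))


def write_coverage_report(records: Iterable[CoverageRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("GENE\tN_TOTAL\tN_COMMON\tN_TYPED\tN_TAGGED\tCOV_RATE\n")
        for r in records:
            rate = "-" if r.coverage_rate is None else f"{r.coverage_rate:.2f}"
            fh.write(f"{r.gene_id}\t{r.n_total}\t{r.n_common}\t{r.n_typed}\t{r.n_tagged}\t{rate}\n")
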