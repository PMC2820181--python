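"""Readers and writers for genotype, phenotype, gene and gene-set files.

Supported genotype dialects are the PLINK text pair (``.ped``/``.map``) and
the transposed additive-dosage table produced by ``plink --recode A-transpose``
(``.traw``).  Dosages are stored as floats with ``numpy.nan`` marking missing
genotypes; non-missing values are always in {0, 1, 2} and count copies of the
effect allele (``allele_b``).
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT0")
MISSING_PHENO_TOKENS = {"NA", "na", "NaN", "nan", "-9", "-9.0"}


class InputError(ValueError):
    """Malformed or inconsistent input file."""


@dataclass(frozen=True)
class SnpRecord:
    """One SNP: identifier, 1-based position and allele pair.

    ``allele_b`` is the counted (effect) allele of the dosage coding;
    ``"0"`` stands for an unknown allele.
    """

    snp_id: str
    chrom: str
    pos: int
    allele_a: str = "0"
    allele_b: str = "0"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError(f"SNP {self.snp_id}: position must be >= 1, got {self.pos}")
        for allele in (self.allele_a, self.allele_b):
            if allele not in VALID_ALLELES:
                raise InputError(f"SNP {self.snp_id}: invalid allele {allele!r}")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs additive dosage matrix with SNP metadata."""

    snps: list[SnpRecord]
    individuals: list[str]
    dosage: np.ndarray  # float64, nan = missing

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.float64)
        if self.dosage.shape != (len(self.individuals), len(self.snps)):
            raise InputError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.snps)} SNPs"
            )
        finite = self.dosage[~np.isnan(self.dosage)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise InputError("dosage values must be 0, 1, 2 or missing")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            dup = [k for k, c in Counter(ids).items() if c > 1]
            raise InputError(f"duplicate snp_id(s): {dup[:5]}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self) -> dict[str, int]:
        return {s.snp_id: j for j, s in enumerate(self.snps)}

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.snp_index()
        missing = [s for s in snp_ids if s not in idx]
        if missing:
            raise InputError(f"unknown snp_id(s): {missing[:5]}")
        cols = [idx[s] for s in snp_ids]
        return GenotypeMatrix(
            snps=[self.snps[j] for j in cols],
            individuals=list(self.individuals),
            dosage=self.dosage[:, cols].copy(),
        )

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {iid: i for i, iid in enumerate(self.individuals)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise InputError(f"unknown individual id(s): {missing[:5]}")
        rows = [pos[i] for i in ids]
        return GenotypeMatrix(
            snps=list(self.snps),
            individuals=list(ids),
            dosage=self.dosage[rows, :].copy(),
        )

    def swap_alleles(self) -> "GenotypeMatrix":
        """Recode dosages to count allele_a instead (d -> 2 - d, missing fixed)."""
        snps = [replace(s, allele_a=s.allele_b, allele_b=s.allele_a) for s in self.snps]
        return GenotypeMatrix(snps=snps, individuals=list(self.individuals), dosage=2.0 - self.dosage)

    def digest(self) -> str:
        """SHA-256 of the dosage bytes; used to assert LD preservation."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.dosage).tobytes())
        return h.hexdigest()


@dataclass
class PhenotypeTable:
    """Quantitative trait (nan = missing) with optional collection-site labels."""

    individual_ids: list[str]
    trait: np.ndarray
    site: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.trait = np.asarray(self.trait, dtype=np.float64)
        if not self.site:
            self.site = ["all"] * len(self.individual_ids)
        if not (len(self.individual_ids) == self.trait.size == len(self.site)):
            raise InputError("phenotype columns have inconsistent lengths")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise InputError("duplicate individual ids in phenotype table")

    def __len__(self) -> int:
        return len(self.individual_ids)


@dataclass(frozen=True)
class GeneRegion:
    """Gene interval, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in {"+", "-", "unknown"}:
            raise InputError(f"gene {self.gene_id}: strand must be +, - or unknown")


@dataclass(frozen=True)
class GeneGroup:
    group_name: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise InputError(f"gene group {self.group_name!r} is empty")


# ---------------------------------------------------------------------------
# genotype readers


def _read_map(path: Path) -> list[tuple[str, str, int]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) not in (3, 4):
                raise InputError(f"{path}:{lineno}: expected 3 or 4 columns, got {len(parts)}")
            chrom, snp_id = parts[0], parts[1]
            pos = int(parts[-1])
            out.append((chrom, snp_id, pos))
    if not out:
        raise InputError(f"{path}: empty map file")
    return out


def _read_ped_map(prefix: Path) -> GenotypeMatrix:
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    sites = _read_map(map_path)
    m = len(sites)
    individuals: list[str] = []
    geno_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise InputError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} columns for {m} SNPs, got {len(parts)}"
                )
            individuals.append(parts[1])
            alleles = parts[6:]
            bad = [a for a in alleles if a not in VALID_ALLELES]
            if bad:
                raise InputError(f"{ped_path}:{lineno}: invalid allele token {bad[0]!r}")
            geno_rows.append(alleles)
    if not individuals:
        raise InputError(f"{ped_path}: empty ped file")

    n = len(individuals)
    allele_arr = np.array(geno_rows, dtype="U1").reshape(n, m, 2)
    dosage = np.full((n, m), np.nan)
    snps: list[SnpRecord] = []
    for j, (chrom, snp_id, pos) in enumerate(sites):
        col = allele_arr[:, j, :]
        observed = col[col != "0"]
        counts = Counter(observed.tolist())
        if len(counts) > 2:
            raise InputError(f"{ped_path}: SNP {snp_id} has more than two alleles: {sorted(counts)}")
        if counts:
            # counted allele = minor allele; frequency ties break to the
            # alphabetically later allele so the choice is deterministic
            allele_b = min(counts, key=lambda a: (counts[a], [-ord(c) for c in a]))
            others = [a for a in counts if a != allele_b]
            allele_a = others[0] if others else "0"
        else:
            allele_a = allele_b = "0"
        missing = (col == "0").any(axis=1)
        dosage[:, j] = (col == allele_b).sum(axis=1)
        dosage[missing, j] = np.nan
        snps.append(SnpRecord(snp_id, chrom, pos, allele_a, allele_b))
    return GenotypeMatrix(snps=snps, individuals=individuals, dosage=dosage)


def _read_traw(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        if header[:6] != ["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"]:
            raise InputError(f"{path}:1: not a traw header: {header[:6]}")
        individuals = header[6:]
        if not individuals:
            raise InputError(f"{path}: no individual columns")
        snps: list[SnpRecord] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + len(individuals):
                raise InputError(
                    f"{path}:{lineno}: expected {6 + len(individuals)} columns, got {len(parts)}"
                )
            chrom, snp_id, _cm, pos, counted, alt = parts[:6]
            snps.append(SnpRecord(snp_id, chrom, int(pos), alt, counted))
            vals = np.array([np.nan if v in ("NA", "nan") else float(v) for v in parts[6:]])
            rows.append(vals)
    if not snps:
        raise InputError(f"{path}: no SNP rows")
    dosage = np.vstack(rows).T
    return GenotypeMatrix(snps=snps, individuals=individuals, dosage=dosage)


def read_genotypes(path_prefix: str | Path, dialect: str = "ped_map") -> GenotypeMatrix:
    """Read genotypes from ``prefix.ped``/``prefix.map`` or ``prefix.traw``.

    Dosage counts copies of ``allele_b``.  For the ped/map dialect the counted
    allele is the minor allele observed in the file (frequency ties broken to
    the alphabetically later allele); the traw dialect carries the counted
    allele explicitly in its COUNTED column.
    """
    prefix = Path(path_prefix)
    if dialect == "ped_map":
        return _read_ped_map(prefix)
    if dialect == "traw":
        path = prefix if prefix.suffix == ".traw" else prefix.with_suffix(".traw")
        return _read_traw(path)
    raise InputError(f"unknown genotype dialect {dialect!r}")


def write_traw(geno: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"] + list(geno.individuals)) + "\n")
        for j, s in enumerate(geno.snps):
            col = geno.dosage[:, j]
            tokens = ["NA" if np.isnan(v) else str(int(v)) for v in col]
            fh.write("\t".join([s.chrom, s.snp_id, "0", str(s.pos), s.allele_b, s.allele_a] + tokens) + "\n")


def write_ped_map(geno: GenotypeMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for s in geno.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, iid in enumerate(geno.individuals):
            fields = [iid, iid, "0", "0", "0", "-9"]
            for j, s in enumerate(geno.snps):
                d = geno.dosage[i, j]
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [s.allele_a, s.allele_a]
                elif d == 1:
                    fields += [s.allele_a, s.allele_b]
                else:
                    fields += [s.allele_b, s.allele_b]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# phenotype / gene / gene-set readers


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a whitespace-delimited trait table with header ID TRAIT [SITE].

    The trait is parsed as a real number; ``NA`` and ``-9`` mark missing
    values (kept as nan, never silently zeroed).  Without a SITE column all
    individuals share one default site label.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty phenotype file") from None
    if df.shape[1] < 2:
        raise InputError(f"{path}: need at least ID and TRAIT columns")
    if df.empty:
        raise InputError(f"{path}: phenotype file has a header but no rows")
    ids = df.iloc[:, 0].astype(str).tolist()
    trait = np.empty(len(df))
    for i, tok in enumerate(df.iloc[:, 1]):
        tok = str(tok)
        if tok in MISSING_PHENO_TOKENS:
            trait[i] = np.nan
            continue
        try:
            trait[i] = float(tok)
        except ValueError:
            raise InputError(f"{path}: row {i + 2}: non-numeric trait value {tok!r}") from None
    site = df.iloc[:, 2].astype(str).tolist() if df.shape[1] >= 3 else []
    return PhenotypeTable(individual_ids=ids, trait=trait, site=site)


def read_gene_regions(path: str | Path) -> list[GeneRegion]:
    """Read a gene table TSV: GENE CHR START END STRAND (1-based inclusive)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty gene table") from None
    if df.shape[1] < 4:
        raise InputError(f"{path}: need GENE CHR START END [STRAND] columns")
    genes = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), 2):
        gene_id = str(row[0])
        if gene_id in seen:
            raise InputError(f"{path}: row {i}: duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        strand = str(row[4]) if len(row) >= 5 and str(row[4]) in {"+", "-"} else "+"
        genes.append(GeneRegion(gene_id, str(row[1]), int(row[2]), int(row[3]), strand))
    return genes


def read_gene_groups(path: str | Path) -> list[GeneGroup]:
    """Read GMT gene sets: name, description, then member gene ids, tab-separated.

    Duplicate gene ids within one line are collapsed.
    """
    groups = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: GMT line needs name, description and >= 1 gene")
            name = parts[0]
            gene_ids = frozenset(g for g in parts[2:] if g)
            if not gene_ids:
                raise InputError(f"{path}:{lineno}: group {name!r} has an empty gene list")
            groups.append(GeneGroup(group_name=name, gene_ids=gene_ids))
    if not groups:
        raise InputError(f"{path}: no gene sets found")
    return groups


# ---------------------------------------------------------------------------
# result writers


def write_group_results(results: Iterable, path: str | Path, alpha: float = 0.05) -> None:
    """Write group results as a TSV ordered by empirical p ascending."""
    rows = sorted(results, key=lambda r: (r.emp_p, r.group_name))
    n_groups = max(len(rows), 1)
    threshold = alpha / n_groups
    with open(path, "w") as fh:
        fh.write("group\tn_genes\tn_snps\tsum_neglog10\temp_p\tn_perm\tsignificant_after_bonferroni\n")
        for r in rows:
            fh.write(
                f"{r.group_name}\t{r.n_genes}\t{r.n_snps}\t{r.sum_stat:.6g}\t"
                f"{r.emp_p:.6g}\t{r.n_perm}\t{'yes' if r.emp_p < threshold else 'no'}\n"
            )


def write_snp_results(results: Iterable, path: str | Path, snp_meta: dict[str, SnpRecord] | None = None,
                      p_gc: dict[str, float] | None = None) -> None:
    """Write per-SNP association results as a TSV."""
    with open(path, "w") as fh:
        fh.write("SNP\tCHR\tPOS\tN\tBETA\tSE\tT\tP\tP_GC\n")
        for r in results:
            meta = snp_meta.get(r.snp_id) if snp_meta else None
            chrom = meta.chrom if meta else "."
            pos = meta.pos if meta else 0
            pgc = p_gc.get(r.snp_id, np.nan) if p_gc else np.nan
            if r.valid:
                fh.write(
                    f"{r.snp_id}\t{chrom}\t{pos}\t{r.n_used}\t{r.beta:.6g}\t{r.se:.6g}\t"
                    f"{r.t_stat:.6g}\t{r.p:.6g}\t{pgc:.6g}\n"
                )
            else:
                fh.write(f"{r.snp_id}\t{chrom}\t{pos}\t{r.n_used}\tNA\tNA\tNA\tNA\tNA\n")
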