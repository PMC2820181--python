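"""Synthetic LD-blocked studies with planted group effects.

Genotypes come from latent-Gaussian AR(1) haplotypes: within a block, each
haploid draw is an AR(1) Gaussian vector thresholded at the quantile implied
by a per-SNP minor allele frequency, and two haploid draws sum to the
dosage.  Blocks are independent, so within-block LD is tunable through one
parameter while the genome-wide structure stays simple.  Each gene spans the
SNPs of one block; groups of genes receive a total planted trait variance
that is split equally over their SNPs (standardized dosage scale), mirroring
a many-small-effects architecture.  Optional collection-site structure adds
a site mean shift to the trait and/or site-dependent allele frequencies, so
stratification confounds can be planted and corrected on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .annotation import build_group_index, map_snps_to_genes
from .genotype_io import (
    GeneGroup,
    GeneRegion,
    GenotypeMatrix,
    PhenotypeTable,
    SnpRecord,
    write_traw,
)

BLOCK_STRIDE_BP = 1_000_000  # blocks far apart so extended gene regions never touch
SNP_SPACING_BP = 100


@dataclass(frozen=True)
class GroupSpec:
    """One planted gene group: name, member-gene count, total variance explained."""

    name: str
    n_genes: int
    planted_r2: float = 0.0


@dataclass
class SimConfig:
    n_individuals: int = 500
    n_blocks: int = 20
    snps_per_block: int = 5
    ld_rho: float = 0.6
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_genes: int | None = None  # default: every block genic
    group_spec: list[GroupSpec] = field(default_factory=list)
    n_sites: int = 1
    site_shift: float = 0.0  # trait-unit mean offset per site index
    site_af_shift: float = 0.0  # +/- MAF offset alternating by site
    trait_mean: float = 100.7
    trait_sd: float = 15.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.snps_per_block < 1:
            raise ValueError("snps_per_block must be >= 1")
        if self.n_genes is None:
            self.n_genes = self.n_blocks
        if self.n_genes > self.n_blocks:
            raise ValueError("n_genes cannot exceed n_blocks")
        total_r2 = sum(g.planted_r2 for g in self.group_spec)
        if total_r2 >= 1:
            raise ValueError("planted r2 values must sum to < 1")


@dataclass
class TruthTable:
    """Ground truth of a simulated study."""

    causal_effects: dict[str, float]  # snp_id -> beta (trait units per allele)
    group_genes: dict[str, list[str]]
    sites: list[str]


def site_labels(config: SimConfig) -> list[str]:
    n = config.n_individuals
    k = max(config.n_sites, 1)
    return [f"site{(i * k) // n}" for i in range(n)]


def _block_snp_ids(config: SimConfig, block: int) -> list[str]:
    return [f"rs{block}_{j}" for j in range(config.snps_per_block)]


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """LD-blocked diallelic dosages; blocks independent, AR(1) LD within.

    The returned matrix carries a ``target_maf`` attribute with the per-SNP
    minor allele frequencies the thresholding aimed for (before any per-site
    offset), for parameter-recovery checks.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    m_block = config.snps_per_block
    rho = config.ld_rho
    sites = site_labels(config)
    site_idx = np.array([int(s[4:]) for s in sites])

    snps: list[SnpRecord] = []
    cols: list[np.ndarray] = []
    all_mafs: list[np.ndarray] = []
    for b in range(config.n_blocks):
        mafs = rng.uniform(*config.maf_range, size=m_block)
        all_mafs.append(mafs)
        # per-site MAF offset (alternating sign) plants a stratification
        # confound; thresholds computed once per (site, SNP), not per person
        if config.site_af_shift != 0.0 and config.n_sites > 1:
            site_deltas = np.where(np.arange(config.n_sites) % 2 == 0, -1.0, 1.0) * config.site_af_shift
            maf_site = np.clip(mafs[None, :] + site_deltas[:, None], 0.01, 0.99)
            thresholds = norm.ppf(maf_site)[site_idx, :]
        else:
            thresholds = np.broadcast_to(norm.ppf(mafs), (n, m_block))

        dose = np.zeros((n, m_block))
        for _hap in range(2):
            z = np.empty((n, m_block))
            z[:, 0] = rng.standard_normal(n)
            for j in range(1, m_block):
                z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho * rho) * rng.standard_normal(n)
            dose += (z < thresholds).astype(float)
        cols.append(dose)
        offset = b * BLOCK_STRIDE_BP + 1
        for j, snp_id in enumerate(_block_snp_ids(config, b)):
            snps.append(SnpRecord(snp_id, "1", offset + j * SNP_SPACING_BP, "A", "G"))

    individuals = [f"ind{i:05d}" for i in range(n)]
    geno = GenotypeMatrix(snps=snps, individuals=individuals, dosage=np.hstack(cols))
    geno.target_maf = np.concatenate(all_mafs)
    return geno


def simulate_annotation(config: SimConfig) -> tuple[list[GeneRegion], list[GeneGroup]]:
    """One gene per block plus named groups; a null group is always emitted.

    Genes are allocated to the configured group specs in order; leftover
    genes form the designated ``null`` group with no planted effects.
    """
    genes = []
    for g in range(config.n_genes):
        start = g * BLOCK_STRIDE_BP + 1
        end = start + (config.snps_per_block - 1) * SNP_SPACING_BP
        genes.append(GeneRegion(f"gene{g}", "1", start, end, "+"))

    need = sum(spec.n_genes for spec in config.group_spec)
    if need >= config.n_genes:
        raise ValueError(
            f"group specs request {need} genes but only {config.n_genes} exist "
            "(at least one gene must remain for the null group)"
        )
    groups = []
    cursor = 0
    for spec in config.group_spec:
        member = frozenset(f"gene{g}" for g in range(cursor, cursor + spec.n_genes))
        cursor += spec.n_genes
        groups.append(GeneGroup(spec.name, member))
    null_member = frozenset(f"gene{g}" for g in range(cursor, config.n_genes))
    groups.append(GeneGroup("null", null_member))
    return genes, groups


def make_truth(genotypes: GenotypeMatrix, genes: list[GeneRegion], groups: list[GeneGroup],
               config: SimConfig) -> TruthTable:
    """Causal-SNP bookkeeping: all SNPs of a planted group's genes are causal.

    Effect sizes are filled in by :func:`simulate_trait` once the realized
    genetic variance is known; here they are initialized to 0.
    """
    assignments = map_snps_to_genes(genotypes.snps, genes)
    indexes = {ix.group_name: ix for ix in build_group_index(assignments, groups)}
    planted = {spec.name: spec.planted_r2 for spec in config.group_spec if spec.planted_r2 > 0}
    causal: dict[str, float] = {}
    for name in planted:
        for snp_id in indexes[name].snp_ids:
            causal[snp_id] = 0.0
    group_genes = {g.group_name: sorted(g.gene_ids) for g in groups}
    return TruthTable(causal_effects=causal, group_genes=group_genes, sites=site_labels(config))


def simulate_trait(genotypes: GenotypeMatrix, truth: TruthTable, config: SimConfig,
                   genes: list[GeneRegion] | None = None,
                   groups: list[GeneGroup] | None = None) -> PhenotypeTable:
    """Trait with planted per-group variance, site shifts and Gaussian noise.

    Each planted group's genetic score is an equal-weight sum of its SNPs'
    standardized dosages, scaled so the group explains exactly its planted
    share of the pre-rescaling trait variance; the whole trait is then
    affinely rescaled to the configured mean and SD (R-squared is affine-
    invariant, so planted shares survive the rescaling).  Realized per-allele
    effect sizes are written back into ``truth.causal_effects``.
    """
    rng = np.random.default_rng(config.seed + 1)  # independent of the genotype stream
    n = genotypes.n_individuals
    if genes is None or groups is None:
        genes, groups = simulate_annotation(config)
    assignments = map_snps_to_genes(genotypes.snps, genes)
    indexes = {ix.group_name: ix for ix in build_group_index(assignments, groups)}
    col = genotypes.snp_index()

    planted = [(spec.name, spec.planted_r2) for spec in config.group_spec if spec.planted_r2 > 0]
    total_r2 = sum(r2 for _, r2 in planted)

    genetic = np.zeros(n)
    scale_per_snp: dict[str, float] = {}
    for name, r2 in planted:
        snp_ids = indexes[name].snp_ids
        score = np.zeros(n)
        per_snp_sd: dict[str, float] = {}
        for s in snp_ids:
            d = genotypes.dosage[:, col[s]]
            sd = d.std()
            if sd == 0:
                continue
            score += (d - d.mean()) / sd
            per_snp_sd[s] = sd
        sd_score = score.std()
        if sd_score == 0:
            continue
        scale = np.sqrt(r2) / sd_score
        genetic += scale * score
        for s, sd in per_snp_sd.items():
            scale_per_snp[s] = scale / sd  # beta on the standardized trait scale

    site_idx = np.array([int(s[4:]) for s in truth.sites])
    shift = (config.site_shift / config.trait_sd) * site_idx
    noise = np.sqrt(max(1.0 - total_r2, 1e-12)) * rng.standard_normal(n)
    y0 = genetic + shift + noise

    sd0 = y0.std()
    y = config.trait_mean + config.trait_sd * (y0 - y0.mean()) / sd0
    for s, b in scale_per_snp.items():
        truth.causal_effects[s] = b * config.trait_sd / sd0
    return PhenotypeTable(individual_ids=list(genotypes.individuals), trait=y, site=list(truth.sites))


@dataclass
class SimStudy:
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    genes: list[GeneRegion]
    groups: list[GeneGroup]
    truth: TruthTable
    config: SimConfig


def simulate_study(config: SimConfig) -> SimStudy:
    """Full seeded study: genotypes, annotation, groups, trait and truth."""
    genotypes = simulate_genotypes(config)
    genes, groups = simulate_annotation(config)
    truth = make_truth(genotypes, genes, groups, config)
    phenotypes = simulate_trait(genotypes, truth, config, genes, groups)
    return SimStudy(genotypes, phenotypes, genes, groups, truth, config)


def write_study(study: SimStudy, outdir: str | Path) -> dict[str, Path]:
    """Emit a study as plain-text files; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / "study.traw",
        "phenotypes": outdir / "phenotypes.tsv",
        "genes": outdir / "genes.tsv",
        "groups": outdir / "groups.gmt",
        "truth": outdir / "truth.tsv",
    }
    write_traw(study.genotypes, paths["genotypes"])
    with open(paths["phenotypes"], "w") as fh:
        fh.write("ID\tTRAIT\tSITE\n")
        for iid, t, s in zip(study.phenotypes.individual_ids, study.phenotypes.trait, study.phenotypes.site):
            fh.write(f"{iid}\t{t:.10g}\t{s}\n")
    with open(paths["genes"], "w") as fh:
        fh.write("GENE\tCHR\tSTART\tEND\tSTRAND\n")
        for g in study.genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\n")
    with open(paths["groups"], "w") as fh:
        for grp in study.groups:
            fh.write("\t".join([grp.group_name, "simulated"] + sorted(grp.gene_ids)) + "\n")
    with open(paths["truth"], "w") as fh:
        fh.write("SNP\tBETA\n")
        for s, b in sorted(study.truth.causal_effects.items()):
            fh.write(f"{s}\t{b:.10g}\n")
    return paths
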