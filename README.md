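# groupgwas

Self-contained gene-group association testing for quantitative-trait GWAS.

Given per-individual SNP dosages, a quantitative trait, gene annotations and
named gene sets, `groupgwas` tests each gene group by summing `-log10` of the
per-SNP linear-regression p-values over all SNPs annotated to the group's
genes, and calibrates that sum against an empirical null obtained by permuting
phenotypes over genotypes.  Because only the phenotype labels move, every
permutation sees the identical genotype matrix — the same SNP counts, LD
structure and sample size — so the empirical p-value is conditional on exactly
those nuisance factors.

Supporting machinery:

- **Annotation** — SNPs are assigned to genes whose strand-aware extended
  region (default 2 kb upstream, 500 bp downstream) contains them; SNPs in
  several regions go to every one of them.
- **Association** — per-SNP OLS with additive dosage coding, genomic-control
  lambda estimation/adjustment, within-site trait Z-standardization, and Q-Q
  data computation.
- **LD coverage** — pairwise dosage-r² tagging and per-gene
  (typed + tagged) / common coverage rates.
- **Power** — single-locus QTL power, minimal detectable variance explained
  and required sample size under a 1-df non-central chi-square model.
- **Synthetic data** — seeded LD-blocked genotype/trait studies with planted
  group effects and optional collection-site confounds, so the whole pipeline
  is testable without restricted genotype data.

## File formats

- Genotypes: PLINK text `.ped`/`.map` pair, or a transposed additive-dosage
  table (`.traw`, header `CHR SNP (C)M POS COUNTED ALT` + one column per
  individual, `NA` = missing).
- Phenotypes: whitespace-delimited `ID TRAIT [SITE]` with header; `NA`/`-9`
  = missing trait.
- Genes: TSV `GENE CHR START END STRAND`, 1-based inclusive.
- Gene sets: GMT (name, description, member gene ids, tab-separated).

## CLI

```sh
# full pipeline: annotate -> scan -> permute -> correct -> report
groupgwas run-groups --geno study --dialect ped_map --pheno pheno.tsv \
    --genes genes.tsv --sets sets.gmt --nperm 10000 --seed 1 \
    --site-z --gc --escalate --out results/

# individual stages
groupgwas annotate --geno study --genes genes.tsv --sets sets.gmt --out ann/
groupgwas assoc --geno study --pheno pheno.tsv --out snps.tsv
groupgwas coverage --reference panel.traw --typed typed_ids.txt --genes genes.tsv --out cov.tsv
groupgwas power --n 627 --alpha 0.0022 --power 0.80     # minimal detectable r2
groupgwas power --n 1507 --r2 0.033 --alpha 0.05        # achieved power
groupgwas simulate --config sim.yaml --out study/
groupgwas report --snp-results snps.tsv --out qq.tsv --plot qq.png
```

`run-groups` writes `group_results.tsv` (group, gene/SNP counts, observed
sum, empirical p, Bonferroni flag), `snp_results.tsv`, `qq_data.tsv` and a
`manifest.json` with input digests, seed, flags and per-stage counts.

Exit codes: 0 success, 2 input error, 3 numeric failure.

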