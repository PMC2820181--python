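"""Group-level statistic and its phenotype-permutation null.

Per gene group the observed statistic X is the sum of -log10 of the per-SNP
regression p-values over the group's SNPs.  For each permutation the trait
vector is shuffled once over individuals (one shared shuffle serves all
groups), the per-SNP scan recomputed, and the group sums Y collected; the
empirical p-value is the fraction of permutations with Y strictly greater
than X.  Shuffling phenotypes leaves the genotype matrix — and hence every
pairwise LD relationship — untouched, so the null is conditional on the
group's SNP count, LD structure and sample size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .annotation import GroupSnpIndex
from .association import bulk_pvalues, genomic_control_adjust, estimate_lambda
from .genotype_io import GenotypeMatrix, InputError

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


@dataclass
class GroupResult:
    group_name: str
    n_genes: int
    n_snps: int
    sum_stat: float  # observed X
    emp_p: float
    n_perm: int
    perm_exceed: int  # count of Y > X


@dataclass
class PermutationPlan:
    """Number of permutations, RNG seed and the optional escalation rule.

    With escalation enabled, a group whose initial empirical p rests on
    fewer than ``min_exceed`` exceedances is re-run from scratch at
    ``n_perm_escalated`` permutations.
    """

    n_perm: int = 10_000
    seed: int = 0
    escalate: bool = False
    n_perm_escalated: int = 100_000
    min_exceed: int = 20
    smoothed: bool = False  # (b+1)/(N+1) estimator instead of b/N
    chunk_size: int = field(default=256, repr=False)

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def sum_neglog10(pvals) -> float:
    """Sum of -log10 p over a group's SNPs; p-values floored at 1e-300."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("cannot sum an empty p-value list")
    if np.any(np.isnan(p)) or np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    n_floored = int((p < P_FLOOR).sum())
    if n_floored:
        logger.info("%d p-value(s) floored at %.0e", n_floored, P_FLOOR)
    return float(-np.log10(np.maximum(p, P_FLOOR)).sum())


def empirical_p(x_obs: float, y_perm, smoothed: bool = False) -> float:
    """Fraction of permutation draws strictly exceeding the observed X.

    Ties count as non-exceedance, so the estimate may be exactly 0.  The
    +1-smoothed estimator (b+1)/(N+1) is available behind ``smoothed``.
    """
    y = np.asarray(list(y_perm), dtype=float)
    if y.size == 0:
        raise ValueError("empty permutation draw list")
    b = int((y > x_obs).sum())
    if smoothed:
        return (b + 1) / (y.size + 1)
    return b / y.size


def bonferroni_threshold(alpha: float, n_groups: int) -> float:
    """Per-group significance threshold alpha / n_groups."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    return alpha / n_groups


def _perm_indices(seed: int, perm_number: int, n: int) -> np.ndarray:
    # shuffle i derives from (seed, i) so runs are reproducible and chunkable
    return np.random.default_rng([seed, perm_number]).permutation(n)


def _group_sums(
    genotypes: GenotypeMatrix,
    trait: np.ndarray,
    indexes: list[GroupSnpIndex],
    n_perm: int,
    plan: PermutationPlan,
    use_gc: bool,
) -> tuple[np.ndarray, np.ndarray, list[list[str]]]:
    """Observed X per group and (groups x n_perm) permuted Y matrix."""
    union_ids: list[str] = []
    seen: set[str] = set()
    for ix in indexes:
        if not ix.snp_ids:
            raise InputError(f"group {ix.group_name!r} indexes no SNPs")
        for s in ix.snp_ids:
            if s not in seen:
                seen.add(s)
                union_ids.append(s)
    sub = genotypes.subset_snps(union_ids)

    keep = ~np.isnan(trait)
    if keep.sum() < 3:
        raise InputError("fewer than 3 individuals with a non-missing trait")
    G = sub.dosage[keep, :]
    y = trait[keep]
    n = y.size

    p_obs, _ = bulk_pvalues(G, y)
    p_obs = p_obs[:, 0]
    invalid = np.isnan(p_obs)
    if invalid.any():
        logger.info("%d SNP(s) invalid in the observed scan; excluded from group sums", int(invalid.sum()))
    if use_gc:
        lam = estimate_lambda(p_obs[~invalid])

    col_of = {s: j for j, s in enumerate(union_ids)}
    member = np.zeros((len(indexes), len(union_ids)))
    used_ids: list[list[str]] = []
    for g, ix in enumerate(indexes):
        valid_ids = [s for s in ix.snp_ids if not invalid[col_of[s]]]
        if not valid_ids:
            raise InputError(f"group {ix.group_name!r} has no valid SNPs")
        used_ids.append(valid_ids)
        member[g, [col_of[s] for s in valid_ids]] = 1.0

    def neglog_sums(pmat: np.ndarray) -> np.ndarray:
        pm = pmat.copy()
        pm[invalid, :] = 1.0  # excluded SNPs contribute 0 in X and every Y
        if use_gc:
            flat = genomic_control_adjust(pm.ravel(), lam)
            pm = flat.reshape(pm.shape)
        return member @ (-np.log10(np.maximum(pm, P_FLOOR)))

    x_obs = neglog_sums(p_obs[:, None])[:, 0]

    digest_before = sub.digest()
    y_perm = np.empty((len(indexes), n_perm))
    done = 0
    while done < n_perm:
        b = min(plan.chunk_size, n_perm - done)
        shuffles = np.column_stack([y[_perm_indices(plan.seed, done + i, n)] for i in range(b)])
        p_chunk, _ = bulk_pvalues(G, shuffles)
        y_perm[:, done : done + b] = neglog_sums(p_chunk)
        done += b
    if sub.digest() != digest_before:
        raise RuntimeError("genotype matrix was modified during permutation")
    return x_obs, y_perm, used_ids


def permutation_test(
    genotypes: GenotypeMatrix,
    trait: np.ndarray,
    indexes: list[GroupSnpIndex],
    plan: PermutationPlan,
    use_gc: bool = False,
) -> list[GroupResult]:
    """Empirical group p-values by phenotype permutation.

    One shared phenotype shuffle per permutation serves every group.  SNPs
    flagged invalid in the observed scan are excluded from their groups in
    every permutation, keeping X and Y on identical SNP sets.  With
    ``use_gc`` all p-values (observed and permuted) are genomic-control
    adjusted with the lambda estimated from the observed scan, so X and Y
    stay on a common scale.
    """
    trait = np.asarray(trait, dtype=float)
    if trait.size != genotypes.n_individuals:
        raise InputError("trait length does not match genotype individuals")
    nonempty = [ix for ix in indexes if ix.snp_ids]
    if not nonempty:
        raise InputError("no non-empty group indexes")

    x_obs, y_perm, used_ids = _group_sums(genotypes, trait, nonempty, plan.n_perm, plan, use_gc)
    results: list[GroupResult] = []
    for g, ix in enumerate(nonempty):
        exceed = int((y_perm[g] > x_obs[g]).sum())
        emp = empirical_p(x_obs[g], y_perm[g], smoothed=plan.smoothed)
        results.append(
            GroupResult(ix.group_name, ix.n_genes_covered, len(used_ids[g]), float(x_obs[g]), emp, plan.n_perm, exceed)
        )

    if plan.escalate and plan.n_perm_escalated > plan.n_perm:
        needy = [g for g, r in enumerate(results) if r.perm_exceed < plan.min_exceed]
        if needy:
            subset = [nonempty[g] for g in needy]
            x2, y2, used2 = _group_sums(genotypes, trait, subset, plan.n_perm_escalated, plan, use_gc)
            for k, g in enumerate(needy):
                exceed = int((y2[k] > x2[k]).sum())
                emp = empirical_p(x2[k], y2[k], smoothed=plan.smoothed)
                results[g] = GroupResult(
                    subset[k].group_name,
                    subset[k].n_genes_covered,
                    len(used2[k]),
                    float(x2[k]),
                    emp,
                    plan.n_perm_escalated,
                    exceed,
                )
    return results
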