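"""Per-SNP quantitative-trait association and stratification corrections.

The association model is ordinary least squares of the trait on additive
dosage with an intercept; the two-sided p-value comes from the t distribution
with n - 2 degrees of freedom, identical to the Pearson-correlation t-test.
Genomic control converts p-values to 1-df chi-square equivalents, estimates
the inflation factor lambda as the median chi-square over the null median,
and deflates the statistics accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy.stats import chi2

# exact median of the central chi-square with 1 df
CHI2_NULL_MEDIAN = float(chi2.isf(0.5, 1))  # 0.45494...


@dataclass
class SnpAssoc:
    """Result of one SNP regression; ``valid`` is False for monomorphic or
    undersized SNPs, whose statistics are nan."""

    snp_id: str
    n_used: int
    beta: float
    se: float
    t_stat: float
    df: int
    p: float
    chisq: float
    valid: bool = True


@dataclass(frozen=True)
class LambdaEstimate:
    lam: float
    n_snps: int

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError(f"lambda must be positive, got {self.lam}")


def _invalid(snp_id: str, n_used: int) -> SnpAssoc:
    return SnpAssoc(snp_id, n_used, np.nan, np.nan, np.nan, max(n_used - 2, 0), np.nan, np.nan, valid=False)


def fit_snp_regression(dosage: np.ndarray, trait: np.ndarray, snp_id: str = "snp") -> SnpAssoc:
    """OLS of trait on additive dosage with intercept, casewise deletion.

    Individuals missing either value are dropped for this SNP.  Fewer than 3
    complete observations or a constant dosage yields an invalid result.
    """
    dosage = np.asarray(dosage, dtype=float)
    trait = np.asarray(trait, dtype=float)
    if dosage.shape != trait.shape:
        raise ValueError("dosage and trait lengths differ")
    keep = ~np.isnan(dosage) & ~np.isnan(trait)
    x = dosage[keep]
    y = trait[keep]
    n = x.size
    if n < 3 or np.ptp(x) == 0:
        return _invalid(snp_id, n)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    sxy = float(xc @ yc)
    syy = float(yc @ yc)
    beta = sxy / sxx
    rss = max(syy - beta * sxy, 0.0)
    df = n - 2
    sigma2 = rss / df
    if sigma2 == 0.0:
        # perfect fit: p at the numeric floor
        se = 0.0
        t = np.inf if beta > 0 else -np.inf
        p = 1e-300
    else:
        se = float(np.sqrt(sigma2 / sxx))
        t = beta / se
        p = float(2.0 * special.stdtr(df, -abs(t)))
        p = max(p, 1e-300)
    return SnpAssoc(snp_id, n, beta, se, t, df, p, p_to_chisq(p))


def bulk_pvalues(dosage: np.ndarray, traits: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided regression p-values for every SNP x trait-vector pair.

    ``dosage`` is individuals x SNPs (nan = missing, casewise deletion per
    SNP); ``traits`` is individuals x B complete trait columns, typically B
    phenotype permutations.  Returns ``(p, n_used)`` with ``p`` of shape
    (SNPs, B) — nan where a SNP is monomorphic or has < 3 complete
    observations — and per-SNP complete-observation counts.

    Equivalent to calling :func:`fit_snp_regression` per pair; implemented
    with masked cross-products so the permutation engine stays at matrix-
    multiplication speed.
    """
    G = np.asarray(dosage, dtype=float)
    Y = np.asarray(traits, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if np.isnan(Y).any():
        raise ValueError("trait columns must be complete; drop missing-trait individuals first")
    mask = ~np.isnan(G)
    G0 = np.where(mask, G, 0.0)
    M = mask.astype(float)

    n_used = M.sum(axis=0)  # (m,)
    sg = G0.sum(axis=0)
    sgg = (G0 * G0).sum(axis=0)
    sy = M.T @ Y  # (m, B)
    syy = M.T @ (Y * Y)
    sgy = G0.T @ Y

    var_g = n_used * sgg - sg * sg  # (m,)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n_used[:, None] * sgy - sg[:, None] * sy
        var_y = n_used[:, None] * syy - sy * sy
        denom = var_g[:, None] * var_y
        r2 = np.where(denom > 0, cov * cov / np.where(denom > 0, denom, 1.0), np.nan)
        r2 = np.clip(r2, 0.0, 1.0)
        df = n_used[:, None] - 2.0
        t2 = r2 * df / np.maximum(1.0 - r2, 1e-300)
        p = 2.0 * special.stdtr(df, -np.sqrt(t2))
    p = np.maximum(p, 1e-300)
    bad = (n_used < 3) | (var_g <= 0)
    p[bad, :] = np.nan
    return p, n_used.astype(int)


def assoc_scan(genotypes, trait: np.ndarray) -> list[SnpAssoc]:
    """One regression per SNP against an aligned trait vector.

    Individuals with missing trait are dropped for every SNP; missing
    genotypes are dropped per SNP.  Raises if no SNP is analyzable.
    """
    trait = np.asarray(trait, dtype=float)
    if trait.size != genotypes.n_individuals:
        raise ValueError("trait length does not match genotype individuals")
    keep = ~np.isnan(trait)
    G = genotypes.dosage[keep, :]
    y = trait[keep]
    results = [fit_snp_regression(G[:, j], y, snp_id=s.snp_id) for j, s in enumerate(genotypes.snps)]
    if not any(r.valid for r in results):
        raise ValueError("no analyzable SNPs (all monomorphic or undersized)")
    return results


def p_to_chisq(p: float | np.ndarray) -> float | np.ndarray:
    """1-df chi-square equivalent of a p-value: the upper quantile at p."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr <= 0) | (p_arr > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    out = chi2.isf(p_arr, 1)
    return float(out) if np.isscalar(p) else out


def estimate_lambda(pvals) -> LambdaEstimate:
    """Genomic inflation factor: median observed chi-square / null median."""
    p = np.asarray(list(pvals), dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("cannot estimate lambda from an empty p-value list")
    lam = float(np.median(p_to_chisq(p)) / CHI2_NULL_MEDIAN)
    return LambdaEstimate(lam=lam, n_snps=p.size)


def genomic_control_adjust(pvals, lam: LambdaEstimate | float) -> np.ndarray:
    """Deflate test statistics by lambda and return adjusted p-values.

    Lambda below 1 is clipped to 1 (no adjustment), the standard convention.
    """
    lam_value = lam.lam if isinstance(lam, LambdaEstimate) else float(lam)
    lam_value = max(lam_value, 1.0)
    p = np.asarray(list(pvals), dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    out[ok] = chi2.sf(p_to_chisq(p[ok]) / lam_value, 1)
    return out


def site_zscores(trait: np.ndarray, site) -> np.ndarray:
    """Standardize the trait to mean 0, SD 1 separately within each site.

    Removes between-site mean differences so known collection-site structure
    cannot generate spurious association.  Missing trait values stay missing.
    Sites with < 2 non-missing values or zero variance are an error.
    """
    trait = np.asarray(trait, dtype=float)
    site = np.asarray(site)
    if trait.size != site.size:
        raise ValueError("trait and site lengths differ")
    out = np.full_like(trait, np.nan)
    for label in np.unique(site):
        rows = site == label
        vals = trait[rows]
        ok = ~np.isnan(vals)
        if ok.sum() < 2:
            raise ValueError(f"site {label!r} has fewer than 2 non-missing trait values")
        sd = vals[ok].std(ddof=1)
        if sd == 0:
            raise ValueError(f"site {label!r} has zero trait variance")
        out[rows] = (vals - vals[ok].mean()) / sd
    return out


def qq_data(pvals) -> tuple[np.ndarray, np.ndarray]:
    """Expected vs observed -log10 p-value pairs for a Q-Q plot.

    Observed values are sorted descending; the i-th expected value is
    -log10((i - 0.5) / m) for rank i of m.
    """
    p = np.asarray(list(pvals), dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values for Q-Q data")
    m = p.size
    observed = np.sort(-np.log10(np.maximum(p, 1e-300)))[::-1]
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    return expected, observed
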