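"""Single-locus QTL power under a 1-df additive test.

The test of a SNP explaining a proportion ``r2`` of trait variance in ``n``
unrelated individuals is modelled as a non-central chi-square with 1 degree
of freedom and non-centrality n * r2 / (1 - r2), evaluated against the
central chi-square critical value for the chosen significance level.  The
chi-square approximation to the F(1, n-2) test is below reporting precision
at sample sizes in the hundreds.
"""

from __future__ import annotations

from scipy.stats import chi2, ncx2


def _check(n: float, r2: float, alpha: float) -> None:
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if not 0 <= r2 < 1:
        raise ValueError(f"r2 must lie in [0, 1), got {r2}")
    if n < 4:
        raise ValueError(f"n must be >= 4, got {n}")


def power_qtl(n: int, r2: float, alpha: float) -> float:
    """Achieved power to detect a SNP explaining ``r2`` of trait variance."""
    _check(n, r2, alpha)
    crit = chi2.isf(alpha, 1)
    if r2 == 0.0:
        return float(alpha)
    ncp = n * r2 / (1.0 - r2)
    return float(ncx2.sf(crit, 1, ncp))


def min_detectable_r2(n: int, alpha: float, power: float, tol: float = 1e-8) -> float:
    """Smallest variance-explained proportion detectable at the target power.

    Bisection over r2 in (0, 1); power_qtl is strictly increasing in r2.
    """
    _check(n, 0.0, alpha)
    if not alpha < power < 1:
        raise ValueError("target power must lie in (alpha, 1)")
    lo, hi = 0.0, 1.0 - 1e-12
    if power_qtl(n, hi, alpha) < power:
        raise ValueError("target power unattainable for any r2 < 1")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if power_qtl(n, mid, alpha) < power:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def required_n(r2: float, alpha: float, power: float, n_max: int = 100_000_000) -> int:
    """Smallest integer sample size achieving the target power."""
    _check(4, r2, alpha)
    if r2 == 0.0:
        raise ValueError("r2 = 0 gives power alpha for every n; no sample size suffices")
    if not alpha < power < 1:
        raise ValueError("target power must lie in (alpha, 1)")
    lo, hi = 4, 8
    while power_qtl(hi, r2, alpha) < power:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise ValueError(f"required n exceeds {n_max}")
    # invariant: power(hi) >= target, power(lo) may or may not reach it
    while lo < hi:
        mid = (lo + hi) // 2
        if power_qtl(mid, r2, alpha) >= power:
            hi = mid
        else:
            lo = mid + 1
    return hi
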