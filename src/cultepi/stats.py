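"""Nonparametric and exceedance statistics for site vs non-site densities.

Two questions are asked of the data before any model is fitted: do the
population-density distributions of sites and non-sites differ at all
(two-sample Kolmogorov-Smirnov), and is the site median higher
(Mann-Whitney U)?  After fitting, the threshold prediction is probed
directly: given the fraction ``p`` of non-sites lying below the inferred
critical density, how surprising is the observed number of sub-threshold
sites under a binomial draw from the non-site distribution?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln, logsumexp

from .io import SampleSet

__all__ = [
    "ComparisonSummary",
    "SubthresholdResult",
    "ks_two_sample",
    "mann_whitney",
    "compare_distributions",
    "subthreshold_binomial",
    "binomial_tail",
    "cumulative_curves",
]


@dataclass(frozen=True)
class ComparisonSummary:
    """Distributional comparison between site and non-site densities."""

    median_sites: float
    median_nonsites: float
    ks_d: float
    ks_p: float
    mw_u: float
    mw_p: float
    n_sites: int
    n_cells: int


@dataclass(frozen=True)
class SubthresholdResult:
    """Binomial test for a deficit of sites below the critical density.

    ``k`` sites of ``n`` fall below ``threshold``; ``p`` is the
    proportion of non-sites below it; ``tail_probability`` is
    ``P(X <= k)`` for ``X ~ Binomial(n, p)``.
    """

    threshold: float
    k: int
    n: int
    p: float
    tail_probability: float

    def __post_init__(self):
        if not 0 <= self.k <= self.n:
            raise ValueError("k must lie in [0, n]")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def ks_two_sample(densities_sites, densities_nonsites) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    Returns ``(D, p)`` where D is the supremum distance between the two
    empirical CDFs and p the asymptotic two-sided p-value.
    """
    a = np.asarray(densities_sites, dtype=float)
    b = np.asarray(densities_nonsites, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def mann_whitney(densities_sites, densities_nonsites) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with tie correction.

    U counts the pairs in which a site density exceeds a non-site density
    (ties count one half).  The p-value uses the normal approximation
    with continuity and tie correction; exact enumeration is used for
    samples small enough (min(n1, n2) <= 8) that it is cheap and tie-free.
    """
    a = np.asarray(densities_sites, dtype=float)
    b = np.asarray(densities_nonsites, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = np.intersect1d(a, b).size > 0 or (
        a.size != np.unique(a).size or b.size != np.unique(b).size
    )
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_distributions(samples: SampleSet) -> ComparisonSummary:
    """Medians, KS and Mann-Whitney comparison of site vs non-site densities."""
    sites = samples.site_densities()
    nonsites = samples.nonsite_densities()
    d, ks_p = ks_two_sample(sites, nonsites)
    u, mw_p = mann_whitney(sites, nonsites)
    return ComparisonSummary(
        median_sites=float(np.median(sites)),
        median_nonsites=float(np.median(nonsites)),
        ks_d=d, ks_p=ks_p, mw_u=u, mw_p=mw_p,
        n_sites=sites.size, n_cells=sites.size + nonsites.size,
    )


def binomial_tail(k: int, n: int, p: float) -> float:
    """Lower tail P(X <= k) for X ~ Binomial(n, p), computed in log space.

    Accumulates log binomial pmf terms with log-sum-exp so tails of order
    1e-20 keep full relative precision.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p == 0.0:
        return 1.0
    if p == 1.0:
        return 1.0 if k == n else 0.0
    j = np.arange(0, k + 1)
    log_comb = gammaln(n + 1) - gammaln(j + 1) - gammaln(n - j + 1)
    log_terms = log_comb + j * np.log(p) + (n - j) * np.log1p(-p)
    return float(np.exp(logsumexp(log_terms)))


def subthreshold_binomial(
    samples: SampleSet,
    threshold: float,
    inclusive: bool = False,
) -> SubthresholdResult:
    """Deficit test: are there fewer sub-threshold sites than chance allows?

    Counts sites with density strictly below the threshold (``inclusive``
    switches to <=; the same convention is applied to non-sites), takes
    ``p`` as the non-site proportion in the same range at full precision,
    and returns the binomial lower-tail probability of observing that few
    sites were site densities drawn from the non-site distribution.
    """
    sites = samples.site_densities()
    nonsites = samples.nonsite_densities()
    if sites.size == 0:
        raise ValueError("no sites in sample set; sub-threshold test undefined")
    if nonsites.size == 0:
        raise ValueError("no non-sites in sample set")
    if inclusive:
        k = int((sites <= threshold).sum())
        p = float((nonsites <= threshold).mean())
    else:
        k = int((sites < threshold).sum())
        p = float((nonsites < threshold).mean())
    tail = binomial_tail(k, sites.size, p)
    return SubthresholdResult(
        threshold=float(threshold), k=k, n=int(sites.size), p=p,
        tail_probability=tail,
    )


def cumulative_curves(samples: SampleSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Empirical CDFs of density for sites and non-sites on a common support.

    Returns ``(density, F_sites, F_nonsites)``: right-continuous monotone
    step functions evaluated at every distinct observed density, each
    ending at 1.
    """
    sites = np.sort(samples.site_densities())
    nonsites = np.sort(samples.nonsite_densities())
    support = np.unique(np.concatenate([sites, nonsites]))
    f_sites = np.searchsorted(sites, support, side="right") / max(sites.size, 1)
    f_nonsites = (np.searchsorted(nonsites, support, side="right")
                  / max(nonsites.size, 1))
    return support, f_sites, f_nonsites
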