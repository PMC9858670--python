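"""Classical mitochondrial diversity estimators.

Implements the standard summary statistics for a sample of n haploid
sequences under the neutral infinite-sites / infinite-alleles models:

* unbiased haplotype diversity Hd = n(1 - sum p_i^2)/(n - 1) with Nei's
  sampling variance;
* mean pairwise differences theta_pi (per sequence) with Tajima's total
  variance, and per-site nucleotide diversity pi = theta_pi / L_eff;
* Watterson's theta_S = S / a1 from the number of segregating sites, with
  its standard estimator variance;
* the Ewens theta_K, the maximum-likelihood theta under the Ewens sampling
  formula given the observed number of haplotypes K, with an equal-tail
  confidence interval from the exact distribution of K (unsigned Stirling
  numbers of the first kind).

Missing data (``N``/``-``) is handled by pairwise deletion for distances and
an any-two-non-missing rule for segregating sites by default: museum-grade
sequences can be mostly missing, and complete deletion would collapse the
usable length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .alignment import Alignment, GroupAssignment, HaplotypeTable, collapse_haplotypes

__all__ = [
    "DiversitySummary",
    "harmonic_numbers",
    "haplotype_diversity",
    "pairwise_difference_matrix",
    "mean_pairwise_differences",
    "tajima_sd",
    "nucleotide_diversity",
    "segregating_sites",
    "watterson_theta",
    "ewens_expected_k",
    "ewens_theta",
    "ewens_theta_ci",
    "stirling1_unsigned",
    "esf_allele_count_pmf",
    "summarize",
]

_MISSING = (b"N", b"-")


def harmonic_numbers(n: int) -> tuple[float, float]:
    """Return (a1, a2) = (sum_{i=1}^{n-1} 1/i, sum_{i=1}^{n-1} 1/i^2)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    i = np.arange(1, n)
    return float(np.sum(1.0 / i)), float(np.sum(1.0 / i**2))


def haplotype_diversity(counts) -> tuple[float, float]:
    """Unbiased haplotype diversity and its standard deviation.

    Hd = n(1 - sum p_i^2)/(n - 1); the SD is the square root of Nei's
    variance of the estimator.

    Parameters
    ----------
    counts : sequence of int
        Haplotype counts c_1..c_K for one sample, all >= 1.
    """
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or (c < 1).any():
        raise ValueError("counts must be nonempty with all entries >= 1")
    n = c.sum()
    if n < 2:
        raise ValueError("need n >= 2 sequences")
    p = c / n
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    hd = n / (n - 1.0) * (1.0 - s2)
    var = (2.0 / (n * (n - 1.0))) * (
        2.0 * (n - 2.0) * (s3 - s2**2) + s2 - s2**2
    )
    return float(hd), math.sqrt(max(var, 0.0))


def pairwise_difference_matrix(aln: Alignment, deletion: str = "pairwise") -> np.ndarray:
    """Integer matrix of pairwise sequence differences.

    ``pairwise`` deletion counts, per pair, sites where both sequences are
    non-missing and differ; ``complete`` restricts all pairs to sites with no
    missing data in any sequence.
    """
    data = aln.data
    miss = aln.missing_mask
    if deletion == "complete":
        keep = ~miss.any(axis=0)
        data = data[:, keep]
        miss = miss[:, keep]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion policy {deletion!r}")
    n = data.shape[0]
    d = np.zeros((n, n), dtype=np.int64)
    ok = ~miss
    for i in range(n):
        both = ok[i] & ok[i + 1:]
        diff = (data[i] != data[i + 1:]) & both
        d[i, i + 1:] = diff.sum(axis=1)
    return d + d.T


def tajima_sd(theta_pi: float, n: int) -> float:
    """SD of theta_pi from Tajima's total variance.

    Var = (n+1)/(3(n-1)) * theta + 2(n^2+n+3)/(9n(n-1)) * theta^2.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    var = ((n + 1.0) / (3.0 * (n - 1.0))) * theta_pi + (
        2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    ) * theta_pi**2
    return math.sqrt(var)


def mean_pairwise_differences(aln: Alignment, deletion: str = "pairwise") -> tuple[float, float]:
    """theta_pi (mean pairwise differences per sequence) and its SD."""
    n = aln.n
    if n < 2:
        raise ValueError("need n >= 2 sequences")
    d = pairwise_difference_matrix(aln, deletion)
    iu = np.triu_indices(n, k=1)
    theta_pi = float(d[iu].mean())
    return theta_pi, tajima_sd(theta_pi, n)


def nucleotide_diversity(theta_pi: float, sd_theta_pi: float, L_eff: float) -> tuple[float, float]:
    """Per-site nucleotide diversity pi = theta_pi / L_eff (and its SD)."""
    if L_eff <= 0:
        raise ValueError("L_eff must be positive")
    return theta_pi / L_eff, sd_theta_pi / L_eff


def segregating_sites(aln: Alignment, site_policy: str = "any_two_nonmissing") -> int:
    """Number of polymorphic sites S.

    ``any_two_nonmissing`` counts a site when at least two distinct
    non-missing states are observed; ``complete_only`` considers only sites
    with no missing data at all.
    """
    if aln.n < 2:
        raise ValueError("need n >= 2 sequences")
    miss = aln.missing_mask
    if site_policy == "complete_only":
        keep = ~miss.any(axis=0)
        data = aln.data[:, keep]
        return int(sum(len(set(col)) > 1 for col in data.T))
    if site_policy != "any_two_nonmissing":
        raise ValueError(f"unknown site_policy {site_policy!r}")
    s = 0
    for col, m in zip(aln.data.T, miss.T):
        states = set(col[~m])
        if len(states) > 1:
            s += 1
    return s


def watterson_theta(S: int, n: int) -> tuple[float, float]:
    """Watterson's theta_S = S/a1 and the SD of the estimator.

    Var(theta_S) = theta/a1 + a2 theta^2 / a1^2 evaluated at the estimate.
    """
    if S < 0:
        raise ValueError("S must be >= 0")
    a1, a2 = harmonic_numbers(n)
    theta = S / a1
    var = theta / a1 + a2 * theta**2 / a1**2
    return theta, math.sqrt(var)


def ewens_expected_k(theta: float, n: int) -> float:
    """Expected number of haplotypes under the Ewens sampling formula."""
    i = np.arange(n, dtype=float)
    return float(np.sum(theta / (theta + i)))


def ewens_theta(n: int, K: int, on_saturated: str = "error") -> float:
    """Ewens maximum-likelihood theta from the observed haplotype count.

    Solves K = sum_{i=0}^{n-1} theta/(theta+i), a strictly increasing
    function of theta, by bracketed root finding (relative tolerance 1e-10).

    ``K == n`` makes the likelihood unbounded; return ``inf`` when
    ``on_saturated="inf"``, raise otherwise.
    """
    if not 1 <= K <= n:
        raise ValueError(f"K must be in [1, n]; got K={K}, n={n}")
    if K == 1:
        return 0.0
    if K == n:
        if on_saturated == "inf":
            return math.inf
        raise ValueError("K == n: the Ewens MLE is unbounded (pass on_saturated='inf')")
    lo, hi = 1e-10, 1e6
    f = lambda t: ewens_expected_k(t, n) - K
    while f(hi) < 0:  # expand upward; E[K] -> n as theta -> inf
        hi *= 10.0
        if hi > 1e30:
            raise RuntimeError("failed to bracket the Ewens MLE")
    return float(brentq(f, lo, hi, rtol=1e-12, maxiter=200))


@lru_cache(maxsize=64)
def stirling1_unsigned(n: int) -> tuple[int, ...]:
    """Unsigned Stirling numbers of the first kind |s(n, k)| for k = 0..n.

    Exact integers via |s(n,k)| = |s(n-1,k-1)| + (n-1)|s(n-1,k)|.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    row = [1]
    for m in range(1, n + 1):
        prev = row
        row = [0] * (m + 1)
        for k in range(1, m + 1):
            row[k] = prev[k - 1] + (m - 1) * (prev[k] if k <= m - 1 else 0)
    return tuple(row)


@lru_cache(maxsize=64)
def _log_stirling1(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 1..n (index 0 -> k=1), computed in log space."""
    row = np.array([0.0])  # n=1: |s(1,1)| = 1
    for m in range(2, n + 1):
        new = np.full(m, -np.inf)
        new[1:] = row  # |s(m-1, k-1)| term shifted
        with np.errstate(divide="ignore"):
            scaled = row + math.log(m - 1)
        new[: m - 1] = np.logaddexp(new[: m - 1], scaled)
        row = new
    return row


def esf_allele_count_pmf(theta: float, n: int) -> np.ndarray:
    """P(K = k | theta, n) for k = 1..n under the Ewens sampling formula.

    P(K=k) = |s(n,k)| theta^k / (theta (theta+1) ... (theta+n-1)).
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if theta == 0.0:
        p = np.zeros(n)
        p[0] = 1.0
        return p
    k = np.arange(1, n + 1)
    log_rising = float(np.sum(np.log(theta + np.arange(n))))
    logp = _log_stirling1(n) + k * math.log(theta) - log_rising
    return np.exp(logp)


def ewens_theta_ci(n: int, K: int, level: float = 0.95) -> tuple[float, float]:
    """Equal-tail confidence interval for theta from the observed K.

    The lower bound solves P(K >= k_obs | theta) = (1-level)/2 and the upper
    bound P(K <= k_obs | theta) = (1-level)/2, using the exact Ewens
    distribution of the number of haplotypes.  ``K == 1`` pins the lower
    bound at 0; ``K == n`` leaves the upper bound infinite.
    """
    if not 1 <= K <= n:
        raise ValueError(f"K must be in [1, n]; got K={K}, n={n}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = (1.0 - level) / 2.0

    def upper_tail(theta):  # P(K >= K_obs), increasing in theta
        return float(esf_allele_count_pmf(theta, n)[K - 1:].sum())

    def lower_tail(theta):  # P(K <= K_obs), decreasing in theta
        return float(esf_allele_count_pmf(theta, n)[:K].sum())

    if K == 1:
        lo = 0.0
    else:
        hi_b = 1.0
        while upper_tail(hi_b) < alpha:
            hi_b *= 10.0
        lo = float(brentq(lambda t: upper_tail(t) - alpha, 1e-12, hi_b, rtol=1e-10))
    if K == n:
        hi = math.inf
    else:
        hi_b = max(1.0, 2.0 * ewens_theta(n, K, on_saturated="inf"))
        while lower_tail(hi_b) > alpha:
            hi_b *= 10.0
            if hi_b > 1e12:
                raise RuntimeError("failed to bracket upper CI bound")
        hi = float(brentq(lambda t: lower_tail(t) - alpha, 1e-12, hi_b, rtol=1e-10))
    return lo, hi


@dataclass(frozen=True)
class DiversitySummary:
    """All diversity indices for one sample (group x region cell)."""

    group: str
    n: int
    K: int
    S: int
    Hd: float
    sd_Hd: float
    theta_pi: float
    sd_theta_pi: float
    pi: float
    sd_pi: float
    theta_S: float
    sd_theta_S: float
    theta_K: float
    theta_K_ci_low: float
    theta_K_ci_high: float
    a1: float
    a2: float
    L_eff: float
    deletion: str
    site_policy: str
    missing_policy: str

    def as_dict(self) -> dict:
        return asdict(self)


def _effective_length_for_pi(aln: Alignment, deletion: str) -> float:
    """Length used to scale theta_pi to per-site pi.

    Pairwise deletion: mean over pairs of the shared non-missing site count
    (matching the per-pair denominators implicit in the distance matrix);
    complete deletion: number of complete sites.
    """
    miss = aln.missing_mask
    if deletion == "complete":
        return float((~miss.any(axis=0)).sum())
    ok = (~miss).astype(np.int64)
    shared = ok @ ok.T
    iu = np.triu_indices(aln.n, k=1)
    return float(shared[iu].mean())


def summarize(
    aln: Alignment,
    groups: GroupAssignment,
    deletion: str = "pairwise",
    site_policy: str = "any_two_nonmissing",
    missing_policy: str = "strict",
    ci_level: float = 0.95,
) -> list[DiversitySummary]:
    """Per-group diversity summary (one record per group label)."""
    out = []
    for label in groups.labels():
        ids = [i for i in aln.ids if groups.groups.get(i) == label]
        if len(ids) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 sequences")
        sub = aln.subset(ids)
        haps = collapse_haplotypes(sub, missing_policy=missing_policy)
        counts = haps.counts()
        n, K = sub.n, haps.K
        hd, sd_hd = haplotype_diversity(counts)
        tpi, sd_tpi = mean_pairwise_differences(sub, deletion)
        L_eff = _effective_length_for_pi(sub, deletion)
        pi, sd_pi = nucleotide_diversity(tpi, sd_tpi, L_eff)
        S = segregating_sites(sub, site_policy)
        tS, sd_tS = watterson_theta(S, n)
        tK = ewens_theta(n, K, on_saturated="inf")
        lo, hi = ewens_theta_ci(n, K, ci_level)
        a1, a2 = harmonic_numbers(n)
        out.append(DiversitySummary(
            group=label, n=n, K=K, S=S, Hd=hd, sd_Hd=sd_hd,
            theta_pi=tpi, sd_theta_pi=sd_tpi, pi=pi, sd_pi=sd_pi,
            theta_S=tS, sd_theta_S=sd_tS,
            theta_K=tK, theta_K_ci_low=lo, theta_K_ci_high=hi,
            a1=a1, a2=a2, L_eff=L_eff,
            deletion=deletion, site_policy=site_policy,
            missing_policy=missing_policy,
        ))
    return out


def summaries_to_frame(summaries) -> pd.DataFrame:
    """Stack DiversitySummary records into a one-row-per-group DataFrame."""
    return pd.DataFrame([s.as_dict() for s in summaries])
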