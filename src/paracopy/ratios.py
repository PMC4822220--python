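"""Bayesian estimation of variant copy ratios at variable positions.

With k gene copies, the true proportion of the designated allele at a
variable position can only be one of the discrete values j/k, j = 1..k-1
(j = 0 or k would make the position conserved).  Given x reads carrying the
designated allele out of n informative reads, the posterior over j is

    P(j | x, n) ∝ prior(j) · Binomial(x; n, j/k),

computed in log space so coverages up to and beyond 10^6 are handled.  The
MAP candidate is reported both as the designated-allele count j and as the
unordered ratio M:m.

A copy-number-free companion treats the proportion as continuous with a
uniform (0, 1) prior, giving a Beta(x+1, n-x+1) posterior whose equal-tailed
credible interval can be compared against candidate ratio proportions:
an interval that falls strictly *between* two adjacent candidate
proportions without containing either flags data inconsistent with every
discrete ratio (a sign of run- or library-specific bias).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .model import VariantCopyRatio

__all__ = [
    "RatioPosterior",
    "ContinuousPosterior",
    "discrete_posterior",
    "continuous_posterior",
    "ratio_separation_check",
    "consensus_ratio",
]

_TIE_TOL = 1e-9  # log-probability gap below which candidates tie


@dataclass(frozen=True)
class RatioPosterior:
    """Discrete posterior over candidate copy ratios at one site."""

    k: int
    candidates: tuple[int, ...]  # j = copies carrying the designated allele
    posterior: tuple[float, ...]
    map_j: int
    map_probability: float
    tied_js: tuple[int, ...]  # all MAP-tied candidates (len > 1 => indeterminate)

    @property
    def is_indeterminate(self) -> bool:
        return len(self.tied_js) > 1

    @property
    def map_ratio(self) -> VariantCopyRatio:
        """MAP as an unordered M:m ratio."""
        return VariantCopyRatio.from_counts(self.map_j, self.k - self.map_j)

    def probability_of(self, j: int) -> float:
        return self.posterior[self.candidates.index(j)]


@dataclass(frozen=True)
class ContinuousPosterior:
    """Uniform-prior (Beta) posterior for the proportion, with credible interval."""

    x: int
    n: int
    level: float
    credible_interval: tuple[float, float]

    @property
    def mean(self) -> float:
        return (self.x + 1) / (self.n + 2)


def discrete_posterior(
    x: int,
    n: int,
    k: int,
    prior: Sequence[float] | None = None,
) -> RatioPosterior:
    """Posterior over the designated-allele copy count j = 1..k-1.

    Parameters
    ----------
    x, n
        Reads carrying the designated allele, and informative reads total.
    k
        Gene copy number (>= 2).
    prior
        Optional weights over the k-1 candidates (default uniform); need
        not be normalized.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError(f"require 0 <= x <= n, got x={x}, n={n}")
    if k < 2:
        raise ValueError("copy number k must be >= 2")
    candidates = np.arange(1, k)
    if prior is None:
        log_prior = np.zeros(k - 1)
    else:
        prior = np.asarray(prior, dtype=float)
        if prior.shape != (k - 1,) or np.any(prior < 0) or prior.sum() == 0:
            raise ValueError("prior must be k-1 nonnegative weights, not all zero")
        with np.errstate(divide="ignore"):
            log_prior = np.log(prior)
    log_post = log_prior + stats.binom.logpmf(x, n, candidates / k)
    log_post -= logsumexp(log_post)
    post = np.exp(log_post)
    best = log_post.max()
    tied = tuple(int(j) for j, lp in zip(candidates, log_post) if lp >= best - _TIE_TOL)
    map_j = tied[0]
    return RatioPosterior(
        k=k,
        candidates=tuple(int(j) for j in candidates),
        posterior=tuple(float(p) for p in post),
        map_j=map_j,
        map_probability=float(post[map_j - 1]),
        tied_js=tied,
    )


def continuous_posterior(x: int, n: int, level: float = 0.95) -> ContinuousPosterior:
    """Copy-number-free proportion posterior: Beta(x+1, n-x+1), equal-tailed CI."""
    if not 0 <= x <= n:
        raise ValueError(f"require 0 <= x <= n, got x={x}, n={n}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = (1 - level) / 2
    dist = stats.beta(x + 1, n - x + 1)
    return ContinuousPosterior(
        x=x,
        n=n,
        level=level,
        credible_interval=(float(dist.ppf(alpha)), float(dist.ppf(1 - alpha))),
    )


def ratio_separation_check(
    cp: ContinuousPosterior, k: int, j_hi: int, j_lo: int
) -> str:
    """Locate the credible interval relative to two candidate proportions.

    Returns one of ``contains_both``, ``contains_hi``, ``contains_lo``,
    ``between`` (interval strictly inside the open gap (j_lo/k, j_hi/k),
    containing neither — the anomaly flag for data displaced from every
    discrete ratio), or ``outside``.
    """
    if not j_hi > j_lo:
        raise ValueError("require j_hi > j_lo")
    p_hi, p_lo = j_hi / k, j_lo / k
    lo, hi = cp.credible_interval
    has_hi = lo <= p_hi <= hi
    has_lo = lo <= p_lo <= hi
    if has_hi and has_lo:
        return "contains_both"
    if has_hi:
        return "contains_hi"
    if has_lo:
        return "contains_lo"
    if p_lo < lo and hi < p_hi:
        return "between"
    return "outside"


def consensus_ratio(
    estimates: Sequence[VariantCopyRatio],
) -> VariantCopyRatio | None:
    """Strict-majority consensus over per-dataset MAP ratios (unordered).

    Returns ``None`` when no ratio is supported by more than half of the
    datasets (ties included).
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    tally = Counter((r.major_count, r.minor_count) for r in estimates)
    (winner, votes), = tally.most_common(1)
    if votes * 2 > len(estimates):
        return VariantCopyRatio(*winner)
    return None
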