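"""Maximum-likelihood inference of the gene copy variant combination set.

Each read spanning a window of V variable sites carries one combination
string.  Under the generative model a read is, with probability 1-c, an
exact copy of one of the k gene copies (chosen uniformly), and with
probability c the product of a *chimera event*: two parent copies are drawn
uniformly with replacement, a single breakpoint is drawn over the V-1 gaps
between consecutive variable sites, and the read carries the first parent's
symbols up to the breakpoint and the second parent's after it.  Sequencing
errors at variable positions are not modelled separately; they are absorbed
into c.

For a candidate multiset of k combinations the emission probability of a
string s is therefore

    P(s) = (1-c) · mult(s)/k  +  c · Σ_{i,j,b} [chimera(i,j,b) = s] · w_b / k²

with w_b the breakpoint weights (uniform 1/(V-1) by default, optionally
proportional to the inter-site gap widths).  The observed combination
counts are multinomial given P, and the likely combination set is found by
exhaustive search over multisets of size k drawn from a candidate alphabet
(the observed combinations, optionally extended by their single-site
neighbours), profiling c over a grid.  Ties are broken deterministically:
higher likelihood, then fewer distinct combinations, then lexicographic.
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .model import ParalogueSet, VariableSite
from .observations import CombinationCounts

__all__ = [
    "ChimeraModel",
    "CombinationSetEstimate",
    "emission_distribution",
    "set_log_likelihood",
    "infer_combination_set",
    "combination_proportion_ci",
    "combine_datasets",
    "DEFAULT_C_GRID",
]

DEFAULT_C_GRID = tuple(np.round(np.arange(0, 0.2005, 0.001), 3))

_LL_TOL = 1e-9


@dataclass(frozen=True)
class ChimeraModel:
    """Single-breakpoint chimera formation between two gene copies.

    ``breakpoint_weights`` give the probability of the breakpoint falling
    in each of the V-1 gaps between consecutive variable sites; ``None``
    means uniform.  Parents are ordered and drawn uniformly with
    replacement, so a chimera of identical parents re-emits a true
    combination.
    """

    rate: float
    breakpoint_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.rate < 1:
            raise ValueError(f"chimera rate must be in [0, 1), got {self.rate}")
        if self.breakpoint_weights is not None:
            w = np.asarray(self.breakpoint_weights, float)
            if np.any(w < 0) or w.sum() <= 0:
                raise ValueError("breakpoint weights must be nonnegative, not all zero")

    @staticmethod
    def gap_weights(sites: Sequence[VariableSite]) -> tuple[float, ...]:
        """Breakpoint weights proportional to inter-site gap widths (bp)."""
        positions = [s.position for s in sites]
        gaps = np.diff(positions).astype(float)
        return tuple(gaps / gaps.sum())

    def weights_for(self, n_sites: int) -> np.ndarray:
        if n_sites < 2:
            raise ValueError("chimera breakpoints need at least 2 variable sites")
        if self.breakpoint_weights is None:
            return np.full(n_sites - 1, 1.0 / (n_sites - 1))
        w = np.asarray(self.breakpoint_weights, float)
        if w.size != n_sites - 1:
            raise ValueError(
                f"{w.size} breakpoint weights for {n_sites} sites (need V-1)"
            )
        return w / w.sum()


@dataclass(frozen=True)
class CombinationSetEstimate:
    """ML multiset of k combinations with fitted chimera rate."""

    copies: tuple[str, ...]  # sorted multiset, |copies| = k
    chimera_rate: float
    log_likelihood: float
    ci_per_combination: dict[str, tuple[float, float, float]] = field(
        default_factory=dict
    )  # combination -> (observed proportion, ci_lower, ci_upper)
    ties: tuple[tuple[str, ...], ...] = ()  # co-optimal multisets, if any
    n_candidates: int = 0  # multisets searched

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_likelihood):
            raise ValueError("log likelihood at the optimum must be finite")

    @property
    def k(self) -> int:
        return len(self.copies)

    def multiplicities(self) -> Counter:
        return Counter(self.copies)


def _as_copies(candidate) -> tuple[str, ...]:
    if isinstance(candidate, ParalogueSet):
        return candidate.copies
    return tuple(candidate)


def emission_distribution(
    candidate,
    c: float,
    breakpoint_weights: Sequence[float] | None = None,
) -> dict[str, float]:
    """Probability of every reachable combination string under the mixture.

    ``candidate`` is a :class:`ParalogueSet` (restricted to the window) or a
    plain multiset of combination strings.
    """
    copies = _as_copies(candidate)
    if not copies:
        raise ValueError("candidate multiset is empty")
    k = len(copies)
    v = len(copies[0])
    model = ChimeraModel(rate=c, breakpoint_weights=(
        tuple(breakpoint_weights) if breakpoint_weights is not None else None
    ))
    mult = Counter(copies)
    probs: dict[str, float] = {s: (1 - c) * m / k for s, m in mult.items()}
    if c > 0:
        if v < 2:
            raise ValueError(
                "chimera rate > 0 requires at least 2 variable sites "
                "(no breakpoint exists for V = 1)"
            )
        w = model.weights_for(v)
        for left, right in itertools.product(copies, repeat=2):
            for b in range(1, v):
                s = left[:b] + right[b:]
                probs[s] = probs.get(s, 0.0) + c * w[b - 1] / (k * k)
    return probs


def set_log_likelihood(
    counts: CombinationCounts | Mapping[str, int],
    candidate,
    c: float,
    breakpoint_weights: Sequence[float] | None = None,
) -> float:
    """Multinomial log likelihood of observed counts under a candidate set.

    Returns ``-inf`` when a combination with positive count has zero
    emission probability.
    """
    table = counts.counts if isinstance(counts, CombinationCounts) else dict(counts)
    copies = _as_copies(candidate)
    if table and copies and len(next(iter(table))) != len(copies[0]):
        raise ValueError("combination length mismatch between counts and candidate")
    probs = emission_distribution(copies, c, breakpoint_weights)
    ll = 0.0
    for s, n in table.items():
        if n == 0:
            continue
        p = probs.get(s, 0.0)
        if p == 0.0:
            return float("-inf")
        ll += n * math.log(p)
    return ll


def combination_proportion_ci(
    count: int, total: int, level: float = 0.95
) -> tuple[float, float]:
    """Clopper-Pearson exact binomial confidence interval for a proportion."""
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= count <= total:
        raise ValueError(f"require 0 <= count <= total, got {count}/{total}")
    alpha = 1 - level
    lower = 0.0 if count == 0 else float(stats.beta.ppf(alpha / 2, count, total - count + 1))
    upper = 1.0 if count == total else float(
        stats.beta.ppf(1 - alpha / 2, count + 1, total - count)
    )
    return lower, upper


def combine_datasets(counts_list: Sequence[CombinationCounts]) -> CombinationCounts:
    """Element-wise sum of combination counts over datasets.

    Dataset sizes are deliberately not normalized: the combined consensus is
    weighted toward larger datasets, which also dilutes chimeras present in
    small clone libraries.
    """
    if not counts_list:
        raise ValueError("need at least one dataset")
    window = counts_list[0].window
    for cc in counts_list[1:]:
        if cc.window != window:
            raise ValueError(f"window mismatch: {cc.window} != {window}")
    merged: dict[str, int] = {}
    rejected = 0
    non_spanning = 0
    for cc in counts_list:
        for s, n in cc.counts.items():
            merged[s] = merged.get(s, 0) + n
        rejected += cc.rejected
        non_spanning += cc.non_spanning
    return CombinationCounts(
        window=window, counts=merged, rejected=rejected, non_spanning=non_spanning
    )


# ----------------------------------------------------------------------
# exhaustive ML search


def _single_site_neighbours(
    observed: Iterable[str], sites: Sequence[VariableSite]
) -> set[str]:
    out: set[str] = set()
    for s in observed:
        for i, site in enumerate(sites):
            a, b = site.alleles
            other = b if s[i] == a else a
            out.add(s[:i] + other + s[i + 1 :])
    return out


def infer_combination_set(
    counts: CombinationCounts | Mapping[str, int],
    k: int,
    c_grid: Sequence[float] | str = "grid",
    alphabet: str | Sequence[str] = "observed",
    sites: Sequence[VariableSite] | None = None,
    breakpoint_weights: Sequence[float] | None = None,
    ci_level: float = 0.95,
    max_multisets: int = 500_000,
) -> CombinationSetEstimate:
    """Exhaustive ML search for the likely variant combination set.

    Parameters
    ----------
    counts
        Observed combination tallies over one site window.
    k
        Gene copy number; the estimate is a multiset of exactly k strings.
    c_grid
        Chimera-rate grid to profile over ("grid" = 0 to 0.2 in 0.001
        steps), or an explicit sequence of rates.
    alphabet
        Candidate strings the multiset is drawn from: ``"observed"``
        (default), ``"neighbours"`` (observed plus single-site flips, which
        needs ``sites``), or an explicit sequence.
    max_multisets
        Guard on the candidate-space size; exceeded -> ``ValueError``.
    """
    if isinstance(counts, CombinationCounts):
        table = dict(counts.counts)
    else:
        table = dict(counts)
    table = {s: n for s, n in table.items() if n > 0}
    if not table:
        raise ValueError("no observed combinations to fit")
    if k < 1:
        raise ValueError("k must be >= 1")
    total = sum(table.values())
    if total < k:
        warnings.warn(
            f"only {total} reads with combinations for k={k} copies; "
            "the estimate will be weakly determined",
            stacklevel=2,
        )
    v = len(next(iter(table)))

    if isinstance(alphabet, str):
        if alphabet == "observed":
            letters = sorted(table)
        elif alphabet in ("neighbours", "neighbors"):
            if sites is None:
                raise ValueError("alphabet='neighbours' requires sites")
            letters = sorted(set(table) | _single_site_neighbours(table, sites))
        else:
            raise ValueError(f"unknown alphabet mode {alphabet!r}")
    else:
        letters = sorted(set(alphabet))
        if any(len(s) != v for s in letters):
            raise ValueError("alphabet strings must match combination length")

    n_letters = len(letters)
    n_multisets = math.comb(n_letters + k - 1, k)
    if n_multisets > max_multisets:
        raise ValueError(
            f"candidate space has {n_multisets} multisets of size {k} over "
            f"{n_letters} strings, above the cap {max_multisets}; restrict "
            "the alphabet or raise max_multisets"
        )

    if isinstance(c_grid, str):
        if c_grid != "grid":
            raise ValueError(f"unknown c_grid mode {c_grid!r}")
        grid = np.asarray(DEFAULT_C_GRID, float)
    else:
        grid = np.asarray(sorted(set(float(c) for c in c_grid)), float)
    if grid.size == 0 or np.any((grid < 0) | (grid >= 1)):
        raise ValueError("chimera rates must lie in [0, 1)")
    if v < 2:
        grid = grid[grid == 0.0]
        if grid.size == 0:
            raise ValueError("V = 1 admits no chimera breakpoint; include c = 0")

    observed = sorted(table)
    obs_index = {s: i for i, s in enumerate(observed)}
    cnt = np.array([table[s] for s in observed], float)

    # chimera transfer tensor T[a, b, s]: probability mass (over breakpoints)
    # that parents (letters[a], letters[b]) emit observed string s
    if v >= 2:
        w = ChimeraModel(
            rate=0.0,
            breakpoint_weights=(
                tuple(breakpoint_weights) if breakpoint_weights is not None else None
            ),
        ).weights_for(v)
        T = np.zeros((n_letters, n_letters, len(observed)))
        for a, left in enumerate(letters):
            for b, right in enumerate(letters):
                for bp in range(1, v):
                    s = left[:bp] + right[bp:]
                    i = obs_index.get(s)
                    if i is not None:
                        T[a, b, i] += w[bp - 1]
    else:
        T = np.zeros((n_letters, n_letters, len(observed)))

    # multiplicity matrix over all candidate multisets
    multisets = list(itertools.combinations_with_replacement(range(n_letters), k))
    M = np.zeros((len(multisets), n_letters))
    for row, ms in enumerate(multisets):
        for a in ms:
            M[row, a] += 1

    letter_index = {s: a for a, s in enumerate(letters)}
    A = np.zeros((len(multisets), len(observed)))
    for j, s in enumerate(observed):
        a = letter_index.get(s)
        if a is not None:
            A[:, j] = M[:, a]
    A /= k
    B = np.einsum("na,abs,nb->ns", M, T, M) / (k * k)

    best_ll = np.full(len(multisets), -np.inf)
    best_c = np.zeros(len(multisets))
    with np.errstate(divide="ignore", invalid="ignore"):
        for c in grid:
            P = (1 - c) * A + c * B
            logP = np.where(P > 0, np.log(np.maximum(P, 1e-300)), -np.inf)
            ll = logP @ cnt
            better = ll > best_ll + _LL_TOL
            best_ll[better] = ll[better]
            best_c[better] = c

    top = best_ll.max()
    if not math.isfinite(top):
        raise ValueError("no candidate multiset explains the observed combinations")
    tied_rows = np.nonzero(best_ll >= top - _LL_TOL)[0]

    def sort_key(row: int):
        ms = multisets[row]
        strings = tuple(sorted(letters[a] for a in ms))
        return (len(set(ms)), strings, best_c[row])

    tied_sorted = sorted(tied_rows, key=sort_key)
    winner = tied_sorted[0]
    winner_copies = tuple(sorted(letters[a] for a in multisets[winner]))
    ties = tuple(
        tuple(sorted(letters[a] for a in multisets[r])) for r in tied_sorted[1:]
    )

    ci = {
        s: (table[s] / total, *combination_proportion_ci(table[s], total, ci_level))
        for s in observed
    }
    return CombinationSetEstimate(
        copies=winner_copies,
        chimera_rate=float(best_c[winner]),
        log_likelihood=float(best_ll[winner]),
        ci_per_combination=ci,
        ties=ties,
        n_candidates=len(multisets),
    )
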