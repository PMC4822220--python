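"""Coverage power analysis for variant copy ratio identification.

How many reads must cover a variable position so that the Bayesian MAP
decision identifies the true copy ratio with a target probability?  Under a
uniform prior the MAP decision at coverage n assigns each observed count x
the candidate j maximizing Binomial(x; n, j/k); its exact power at a true
ratio j:(k-j) is the binomial tail mass of the x-region mapped (as an
unordered ratio) to that truth.  Ties count as failures.

``required_coverage`` offers three methods:

* ``"sample-size"`` (default) — closed-form normal-approximation design
  formula.  The MAP decision is, asymptotically, "nearest candidate
  proportion", with decision boundaries half a gap d = 1/(2k) from the true
  proportion p = j/k; requiring the observed proportion to stay within the
  half-gap with two-sigma confidence gives

      n = ceil(z^2 · σ^2 · (2k)^2),  z = 2,

  with σ^2 = p(1-p), except that ratios adjacent to balanced (|2j-k| <= 1,
  whose unordered acceptance region straddles 1/2) use the worst-case
  binomial variance σ^2 = 1/4.  This yields integer coverages
  n = 16·j·(k-j), e.g. 96x for 6:1 of 7 copies and 80x for 5:1 of 6, and
  n = 4k^2 for the near-balanced ratios, e.g. 196x for 4:3 and 144x for
  3:3.
* ``"exact-first"`` — smallest n whose exact power meets the target.
  Exact binomial power is non-monotone in n (sawtooth), so this can return
  an n followed by coverages that dip back below the target.
* ``"exact-stable"`` — smallest n from which the exact power stays at or
  above the target for every larger coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PowerResult", "decision_rule", "power", "required_coverage", "power_table"]

_TIE_TOL = 1e-9

TIE = -1  # decision_rule marker for MAP ties


@dataclass(frozen=True)
class PowerResult:
    """Outcome of a required-coverage computation."""

    k: int
    true_j: int
    target: float
    required_coverage: int
    achieved_power: float  # exact MAP power at required_coverage
    method: str

    @property
    def ratio(self) -> str:
        hi, lo = max(self.true_j, self.k - self.true_j), min(
            self.true_j, self.k - self.true_j
        )
        return f"{hi}:{lo}"


def _validate(k: int, true_j: int | None = None) -> None:
    if k < 2:
        raise ValueError("copy number k must be >= 2")
    if true_j is not None and not 1 <= true_j <= k - 1:
        raise ValueError(f"require 1 <= true_j <= k-1, got {true_j}")


def decision_rule(n: int, k: int) -> np.ndarray:
    """MAP candidate for every observed count x = 0..n (uniform prior).

    Returns an int array of length n+1; entry x is the j maximizing
    Binomial(x; n, j/k), or :data:`TIE` where the maximum is shared.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    _validate(k)
    x = np.arange(n + 1)
    log_l = np.stack([stats.binom.logpmf(x, n, j / k) for j in range(1, k)])
    best = log_l.max(axis=0)
    is_near = log_l >= best[None, :] - _TIE_TOL
    n_best = is_near.sum(axis=0)
    jmap = is_near.argmax(axis=0) + 1  # first (lowest-j) maximizer
    jmap[n_best > 1] = TIE
    return jmap


def power(n: int, k: int, true_j: int, unordered: bool = True) -> float:
    """Exact probability the MAP identifies the true ratio at coverage n.

    Correctness is judged on the unordered ratio by default (MAP j or k-j
    both count); MAP ties never count as correct.
    """
    _validate(k, true_j)
    jmap = decision_rule(n, k)
    correct = jmap == true_j
    if unordered:
        correct |= jmap == k - true_j
    x = np.arange(n + 1)
    return float(stats.binom.pmf(x[correct], n, true_j / k).sum())


def _sample_size(k: int, true_j: int, target: float, z: float | None) -> int:
    if z is None:
        # two-sigma at the default 95% target; general targets fall back to
        # the normal quantile
        z = 2.0 if abs(target - 0.95) < 1e-12 else float(stats.norm.ppf((1 + target) / 2))
    if abs(2 * true_j - k) <= 1:
        # unordered acceptance region straddles 1/2: worst-case variance
        return math.ceil(z * z * k * k - 1e-9)
    # n = z^2 p(1-p) (2k)^2 = 4 z^2 j (k-j) — integer for z = 2
    return math.ceil(4 * z * z * true_j * (k - true_j) - 1e-9)


def _exact_first(k: int, true_j: int, target: float, n_max: int) -> int:
    for n in range(1, n_max + 1):
        if power(n, k, true_j) >= target:
            return n
    raise RuntimeError(f"power target {target} not reached by n = {n_max}")


def _exact_stable(k: int, true_j: int, target: float, n_max: int) -> int:
    last_fail = 0
    for n in range(1, n_max + 1):
        if power(n, k, true_j) < target:
            last_fail = n
    if last_fail >= n_max:
        raise RuntimeError(f"power still below target {target} at n = {n_max}")
    return last_fail + 1


def required_coverage(
    k: int,
    true_j: int,
    target: float = 0.95,
    method: str = "sample-size",
    z: float | None = None,
    n_max: int | None = None,
) -> PowerResult:
    """Coverage needed to identify the true copy ratio with the target probability.

    ``true_j`` may be given as either side of the ratio (j and k-j are
    equivalent).  See the module docstring for the three methods.
    """
    _validate(k, true_j)
    if not 0 < target < 1:
        raise ValueError("target must be in (0, 1)")
    if n_max is None:
        n_max = max(4 * _sample_size(k, true_j, target, z), 500)
    if method == "sample-size":
        n = _sample_size(k, true_j, target, z)
    elif method == "exact-first":
        n = _exact_first(k, true_j, target, n_max)
    elif method == "exact-stable":
        n = _exact_stable(k, true_j, target, n_max)
    else:
        raise ValueError(f"unknown method {method!r}")
    return PowerResult(
        k=k,
        true_j=true_j,
        target=target,
        required_coverage=n,
        achieved_power=power(n, k, true_j),
        method=method,
    )


def power_table(
    k: int, target: float = 0.95, method: str = "sample-size"
) -> list[PowerResult]:
    """Required coverage for every unordered ratio M:m of a copy number."""
    _validate(k)
    return [
        required_coverage(k, j, target=target, method=method)
        for j in range(k - 1, (k - 1) // 2, -1)  # j >= k-j, hardest last
    ]
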