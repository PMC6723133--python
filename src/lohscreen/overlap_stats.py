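"""Overlap statistics between two screens' hit lists.

Two gene-level screens of the same collection rarely call identical hit
lists; the question is whether the overlap they do share exceeds chance.
Given hit lists of sizes ``n1`` and ``n2`` drawn from a common background of
``N`` screened genes, the chance expectation of the overlap is
``n1 * n2 / N`` and the observed count ``k`` follows a hypergeometric
distribution under the null of independent draws.  Two summaries are
reported:

* the **representation factor** ``rf = k / (n1 * n2 / N)`` — values above 1
  indicate more overlap than expected, below 1 less;
* a directional **hypergeometric tail probability** — the upper tail
  ``P(X >= k)`` when the overlap is at or above expectation, the lower tail
  ``P(X <= k)`` otherwise.

The tail direction switches at the expectation so that the reported p is
always the probability of an outcome at least as extreme, in the observed
direction, as the one seen.  A normal approximation to the tail (with or
without continuity correction) is available for comparison, but the exact
summation is the default and is what the package reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Literal

import numpy as np
from scipy.stats import hypergeom, norm

__all__ = [
    "OverlapResult",
    "expected_overlap",
    "representation_factor",
    "overlap_pvalue",
    "overlap_pvalue_normal",
    "compare_screens",
]

Tail = Literal["upper", "lower"]


@dataclass(frozen=True)
class OverlapResult:
    """Overlap between two hit lists on a common background.

    Attributes
    ----------
    k : observed overlap count.
    n1, n2 : hit-list sizes after restriction to the background.
    N : background (total screened genes).
    expected : chance expectation ``n1 * n2 / N``, in genes.
    rf : representation factor ``k / expected`` (dimensionless).
    p : directional hypergeometric tail probability.
    tail : which tail ``p`` is (``"upper"`` iff ``k >= expected``).
    """

    k: int
    n1: int
    n2: int
    N: int
    expected: float
    rf: float
    p: float
    tail: Tail

    def rf_rounded(self, ndigits: int = 1) -> float:
        """Representation factor rounded for reporting (rounding happens
        only here, never inside the computation)."""
        return round(self.rf, ndigits)


def _validate(k: int, n1: int, n2: int, N: int) -> None:
    if N <= 0:
        raise ValueError("background size N must be positive")
    if not (0 < n1 <= N and 0 < n2 <= N):
        raise ValueError(f"hit-list sizes must satisfy 0 < n1, n2 <= N (got {n1}, {n2}, N={N})")
    lo = max(0, n1 + n2 - N)
    hi = min(n1, n2)
    if not lo <= k <= hi:
        raise ValueError(f"overlap k={k} infeasible for n1={n1}, n2={n2}, N={N} (support [{lo}, {hi}])")


def expected_overlap(n1: int, n2: int, N: int) -> float:
    """Expected overlap ``n1 * n2 / N`` between two random gene lists."""
    if N <= 0:
        raise ValueError("background size N must be positive")
    if not (0 < n1 <= N and 0 < n2 <= N):
        raise ValueError("hit-list sizes must satisfy 0 < n1, n2 <= N")
    return n1 * n2 / N


def representation_factor(k: int, n1: int, n2: int, N: int) -> float:
    """Observed overlap divided by its chance expectation.

    Returned at full precision; round only when reporting.
    """
    _validate(k, n1, n2, N)
    exp = expected_overlap(n1, n2, N)
    if exp == 0:
        raise ValueError("expected overlap is zero")
    return k / exp


def overlap_pvalue(k: int, n1: int, n2: int, N: int) -> tuple[float, Tail]:
    """Directional exact hypergeometric tail probability of the overlap.

    With ``X ~ Hypergeometric(N, n1, n2)``: if ``k >= n1*n2/N`` the upper
    tail ``P(X >= k)`` is returned, otherwise the lower tail ``P(X <= k)``.
    Both tails include the observed atom, so ``p(upper) + p(lower) >= 1``.
    """
    _validate(k, n1, n2, N)
    exp = expected_overlap(n1, n2, N)
    if k >= exp:
        return float(hypergeom.sf(k - 1, N, n1, n2)), "upper"
    return float(hypergeom.cdf(k, N, n1, n2)), "lower"


def overlap_pvalue_normal(
    k: int, n1: int, n2: int, N: int, continuity: bool = True
) -> tuple[float, Tail]:
    """Normal approximation to :func:`overlap_pvalue`, for comparison only.

    Uses the hypergeometric mean and variance; ``continuity`` applies the
    usual half-integer correction.
    """
    _validate(k, n1, n2, N)
    mu = expected_overlap(n1, n2, N)
    var = mu * (1 - n1 / N) * (N - n2) / (N - 1)
    sd = np.sqrt(var) if var > 0 else 0.0
    cc = 0.5 if continuity else 0.0
    if sd == 0:
        return (1.0, "upper" if k >= mu else "lower")
    if k >= mu:
        return float(norm.sf((k - cc - mu) / sd)), "upper"
    return float(norm.cdf((k + cc - mu) / sd)), "lower"


def compare_screens(
    hits1: Collection[str],
    hits2: Collection[str],
    background: Collection[str],
) -> OverlapResult:
    """Full overlap analysis of two hit lists on an explicit background.

    Both lists are restricted to ``background`` before counting; a hit gene
    absent from the background is an error (it usually signals mismatched
    identifier conventions), listing the offending genes.
    """
    bg = set(background)
    s1, s2 = set(hits1), set(hits2)
    missing = sorted((s1 | s2) - bg)
    if missing:
        raise ValueError(f"hit genes absent from background: {', '.join(missing)}")
    n1, n2, N = len(s1), len(s2), len(bg)
    k = len(s1 & s2)
    exp = expected_overlap(n1, n2, N)
    rf = k / exp
    p, tail = overlap_pvalue(k, n1, n2, N)
    return OverlapResult(k=k, n1=n1, n2=n2, N=N, expected=exp, rf=rf, p=p, tail=tail)
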