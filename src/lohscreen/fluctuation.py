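"""Luria-Delbruck fluctuation analysis of loss-of-heterozygosity rates.

Parallel cultures grown from small inocula accumulate LOH events at random
times; an event early in growth founds a large resistant clone, a late one
a small clone, so the distribution of resistant-colony counts across
cultures is heavily skewed ("jackpots").  Under the Lea-Coulson model (no
mutant fitness difference, complete plating) the number of mutational
events per culture is Poisson with mean m and each event's clone size has
the 1/(k(k+1)) tail, giving the Luria-Delbruck count distribution whose
probabilities follow the Ma-Sandri-Sarkar recursion

    p_0 = exp(-m),    p_n = (m / n) * sum_{j=0}^{n-1} p_j / (n - j + 1).

m is estimated per strain by maximising the product of these probabilities
over the observed counts; a 95% confidence interval comes from the
chi-square(1) profile-likelihood cut.  The LOH *rate* is m divided by the
final population size N_t, and two strains are called significantly
different when their 95% rate intervals do not overlap — the decision rule
used for the mutant-vs-wildtype benchmarking this module supports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import chi2

__all__ = [
    "JACKPOT_CAP",
    "FluctuationExperiment",
    "RateEstimate",
    "StrainComparison",
    "ld_pmf",
    "log_likelihood",
    "mle_m",
    "profile_ci",
    "loh_rate",
    "estimate_rate",
    "compare_to_reference",
    "select_cultures",
]

# Counts above this are treated as right-censored "jackpots": the O(k^2)
# pmf recursion is kept tractable and the likelihood uses P(X >= cap).
JACKPOT_CAP = 10_000


@dataclass(frozen=True)
class FluctuationExperiment:
    """Per-culture resistant-colony counts for one strain.

    ``n_final`` is the final viable-cell count per culture (scalar or one
    value per culture; the mean is used for rate scaling).
    """

    strain_id: str
    counts: tuple[int, ...]
    n_final: float

    def __post_init__(self) -> None:
        if len(self.counts) == 0:
            raise ValueError("at least one culture required")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if self.n_final <= 0:
            raise ValueError("n_final must be positive")
        if self.n_final <= max(self.counts):
            warnings.warn(
                f"{self.strain_id}: n_final ({self.n_final:g}) does not exceed the "
                f"largest count ({max(self.counts)})",
                stacklevel=2,
            )


@dataclass(frozen=True)
class RateEstimate:
    """MLE of the per-culture mutation number and the derived LOH rate."""

    strain_id: str
    m_hat: float
    m_low: float
    m_high: float
    rate: float
    ci_low: float
    ci_high: float
    loglik: float
    n_cultures: int
    n_jackpots: int = 0


@dataclass(frozen=True)
class StrainComparison:
    """Fold change of a strain's LOH rate over a reference, with the
    CI-overlap significance call (non-overlapping 95% CIs <=> significant)."""

    strain_id: str
    fold_change: float
    significant: bool
    fold_defined: bool = True


def ld_pmf(m: float, k_max: int) -> np.ndarray:
    """Luria-Delbruck probabilities p_0 .. p_{k_max} at mutation number m.

    Ma-Sandri-Sarkar recursion under the Lea-Coulson model.  All entries
    are non-negative and partial sums stay at or below 1; the full series
    sums to 1 as k_max grows.
    """
    if m < 0:
        raise ValueError("m must be non-negative")
    if k_max < 0:
        raise ValueError("k_max must be non-negative")
    p = np.zeros(k_max + 1)
    p[0] = np.exp(-m)
    if k_max == 0:
        return p
    # inv[d] = 1/d ; term for p_j in p_n carries weight 1/(n - j + 1)
    inv = np.empty(k_max + 2)
    inv[0] = np.inf
    inv[1:] = 1.0 / np.arange(1, k_max + 2)
    for n in range(1, k_max + 1):
        p[n] = (m / n) * float(np.dot(p[:n], inv[n + 1 : 1 : -1]))
    return p


def _prepare_counts(counts: Sequence[int]) -> tuple[np.ndarray, int, int]:
    arr = np.asarray(counts, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("at least one count required")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    n_jackpot = int(np.sum(arr > JACKPOT_CAP))
    arr = np.minimum(arr, JACKPOT_CAP)
    return arr, int(arr.max()), n_jackpot


def log_likelihood(m: float, counts: Sequence[int]) -> float:
    """Lea-Coulson log-likelihood of per-culture counts at mutation number m.

    Counts above :data:`JACKPOT_CAP` contribute the censored tail
    P(X >= cap) instead of a point probability.
    """
    arr, k_max, _ = _prepare_counts(counts)
    if m == 0:
        return 0.0 if k_max == 0 else -np.inf
    p = ld_pmf(m, k_max)
    censored = arr >= JACKPOT_CAP
    ll = 0.0
    obs = arr[~censored]
    if obs.size:
        probs = p[obs]
        if np.any(probs <= 0):
            return -np.inf
        ll += float(np.sum(np.log(probs)))
    n_cens = int(censored.sum())
    if n_cens:
        tail = max(1.0 - float(p[:-1].sum()) + float(p[-1]), 0.0)  # P(X >= cap)
        if tail <= 0:
            return -np.inf
        ll += n_cens * np.log(tail)
    return ll


def mle_m(counts: Sequence[int], xatol: float = 1e-6) -> tuple[float, float]:
    """Maximum-likelihood mutation number m_hat and its log-likelihood.

    Bracketed 1-D (Brent) optimisation started from the p0-method value
    -ln(zero fraction) (0.1 when no culture is empty); the bracket is
    widened, with a warning, if the optimum presses against it.
    """
    arr, k_max, _ = _prepare_counts(counts)
    if k_max == 0:
        return 0.0, 0.0  # likelihood exp(-C m) is maximised at the boundary
    zero_frac = float(np.mean(arr == 0))
    m0 = -np.log(zero_frac) if zero_frac > 0 else 0.1
    hi = max(5.0 * m0, 2.0)
    for _ in range(60):
        res = minimize_scalar(
            lambda m: -log_likelihood(m, arr),
            bounds=(0.0, hi),
            method="bounded",
            options={"xatol": xatol},
        )
        if res.x < 0.99 * hi:
            return float(res.x), float(-res.fun)
        hi *= 2.0
        if hi > 1e3:
            warnings.warn(f"likelihood still rising at m = {res.x:.3g}; bracket "
                          f"widened to {hi:.3g}", stacklevel=2)
    return float(res.x), float(-res.fun)


def profile_ci(counts: Sequence[int], alpha: float = 0.05) -> tuple[float, float]:
    """Profile-likelihood confidence interval for the mutation number m.

    Bounds solve 2*[loglik(m_hat) - loglik(m)] = chi2(1) quantile, found by
    root bracketing on each side; the lower bound is clipped at 0.  With
    all-zero counts the likelihood is exp(-C m) and the interval is
    [0, q/(2C)] in closed form.
    """
    arr, k_max, _ = _prepare_counts(counts)
    q = float(chi2.ppf(1.0 - alpha, df=1))
    if k_max == 0:
        return 0.0, q / (2.0 * arr.size)
    m_hat, ll_hat = mle_m(arr)

    def deficit(m: float) -> float:
        return 2.0 * (ll_hat - log_likelihood(m, arr)) - q

    # lower bound
    if m_hat <= 0 or deficit(1e-12) <= 0:
        m_low = 0.0
    else:
        m_low = float(brentq(deficit, 1e-12, m_hat, xtol=1e-9))
    # upper bound: expand until the deficit turns positive
    hi = max(2.0 * m_hat, m_hat + 1.0)
    for _ in range(200):
        if deficit(hi) > 0:
            break
        hi *= 1.6
    m_high = float(brentq(deficit, m_hat, hi, xtol=1e-9))
    return m_low, m_high


def loh_rate(
    m_hat: float, ci: tuple[float, float], n_final: float, strain_id: str = "",
    loglik: float = np.nan, n_cultures: int = 0, n_jackpots: int = 0,
) -> RateEstimate:
    """Scale an m-scale estimate and CI to a per-cell LOH rate (m / N_t)."""
    if n_final <= 0:
        raise ValueError("n_final must be positive")
    m_low, m_high = ci
    return RateEstimate(
        strain_id=strain_id,
        m_hat=m_hat,
        m_low=m_low,
        m_high=m_high,
        rate=m_hat / n_final,
        ci_low=m_low / n_final,
        ci_high=m_high / n_final,
        loglik=loglik,
        n_cultures=n_cultures,
        n_jackpots=n_jackpots,
    )


def estimate_rate(experiment: FluctuationExperiment, alpha: float = 0.05) -> RateEstimate:
    """Full per-strain analysis: MLE, profile CI, rate scaling."""
    arr, _, n_jackpot = _prepare_counts(experiment.counts)
    m_hat, ll = mle_m(arr)
    ci = profile_ci(arr, alpha=alpha)
    return loh_rate(
        m_hat,
        ci,
        float(np.mean(experiment.n_final)),
        strain_id=experiment.strain_id,
        loglik=ll,
        n_cultures=arr.size,
        n_jackpots=n_jackpot,
    )


def compare_to_reference(test: RateEstimate, ref: RateEstimate) -> StrainComparison:
    """Fold change vs a reference strain and the CI-overlap significance call."""
    if ref.rate == 0:
        warnings.warn(f"{ref.strain_id or 'reference'}: zero rate, fold change undefined",
                      stacklevel=2)
        fold, defined = float("nan"), False
    else:
        fold, defined = test.rate / ref.rate, True
    disjoint = test.ci_low > ref.ci_high or test.ci_high < ref.ci_low
    return StrainComparison(
        strain_id=test.strain_id, fold_change=fold, significant=bool(disjoint),
        fold_defined=defined,
    )


def select_cultures(
    od_readings: Sequence[float], n_keep: int = 15, od_min: float = 0.5
) -> list[int]:
    """Pick the ``n_keep`` cultures most similar in size, by optical density.

    Readings at or below ``od_min`` are discarded; among the rest, the
    ``n_keep`` with the smallest absolute deviation from the filtered
    median are kept (ties broken by input order).  Returns original indices
    in input order.
    """
    eligible = [(i, od) for i, od in enumerate(od_readings) if od > od_min]
    if len(eligible) < n_keep:
        raise ValueError(
            f"only {len(eligible)} readings above {od_min}, need {n_keep} "
            f"(short by {n_keep - len(eligible)})"
        )
    med = float(np.median([od for _, od in eligible]))
    ranked = sorted(range(len(eligible)), key=lambda r: (abs(eligible[r][1] - med), r))
    chosen = sorted(eligible[r][0] for r in ranked[:n_keep])
    return chosen
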