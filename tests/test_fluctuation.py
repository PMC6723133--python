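"""Luria-Delbruck pmf, MLE, profile CIs, rate comparison, culture selection."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import chi2

from lohscreen.fluctuation import (
    FluctuationExperiment,
    compare_to_reference,
    estimate_rate,
    ld_pmf,
    log_likelihood,
    loh_rate,
    mle_m,
    profile_ci,
    select_cultures,
)
from lohscreen.synthetic_data import FluctuationSimConfig, simulate_fluctuation


def pmf_reference(m: float, k_max: int) -> np.ndarray:
    """Direct, loop-free re-derivation of the recursion (oracle),
    vectorised over nothing — plain Python floats."""
    p = [math.exp(-m)]
    for n in range(1, k_max + 1):
        p.append((m / n) * sum(p[j] / (n - j + 1) for j in range(n)))
    return np.array(p)


def grid_mle(counts, grid) -> float:
    """Grid-search oracle for the MLE, vectorised over the grid."""
    counts = np.asarray(counts)
    k_max = int(counts.max())
    M = grid.size
    p = np.zeros((M, k_max + 1))
    p[:, 0] = np.exp(-grid)
    inv = 1.0 / np.arange(1, k_max + 2)  # inv[i] = 1/(i+1)
    for n in range(1, k_max + 1):
        w = inv[1 : n + 1][::-1]  # 1/(n-j+1) for j = 0..n-1
        p[:, n] = (grid / n) * (p[:, :n] @ w)
    ll = np.log(np.clip(p[:, counts], 1e-300, None)).sum(axis=1)
    return float(grid[np.argmax(ll)])


class TestLdPmf:
    def test_first_terms_at_unit_m(self):
        p = ld_pmf(1.0, 2)
        assert p[0] == pytest.approx(math.exp(-1), abs=5e-6)   # 0.36788
        assert p[1] == pytest.approx(math.exp(-1) / 2, abs=5e-6)  # 0.18394
        assert p[2] == pytest.approx(0.10730, abs=5e-6)  # (1/2)(p0/3 + p1/2)

    @pytest.mark.parametrize("m", [0.3, 1.0, 4.2])
    def test_matches_reference_recursion(self, m):
        assert np.allclose(ld_pmf(m, 60), pmf_reference(m, 60), rtol=1e-12)

    @pytest.mark.parametrize("m", [0.0, 0.5, 2.0, 10.0])
    def test_partial_sums_approach_one_from_below(self, m):
        p = ld_pmf(m, 2000)
        assert np.all(p >= 0)
        sums = np.cumsum(p)
        assert np.all(sums <= 1 + 1e-12)
        # heavy 1/k^2 tail: deficit at k_max is of order m/k_max
        assert 1 - sums[-1] <= max(2e-12, 1.5 * m / 2000)

    def test_negative_m_rejected(self):
        with pytest.raises(ValueError):
            ld_pmf(-0.1, 5)


class TestMleM:
    def test_all_zero_counts_boundary(self):
        m_hat, ll = mle_m([0] * 12)
        assert m_hat == 0.0 and ll == 0.0

    def test_fixture_matches_grid_oracle(self):
        counts = [0, 0, 1, 3, 0, 2, 14, 0, 1, 0]
        m_hat, _ = mle_m(counts)
        grid = np.arange(0.0001, 5.0, 0.0001)
        assert abs(m_hat - grid_mle(counts, grid)) < 1e-3

    def test_likelihood_unimodal_on_fixture(self):
        counts = [0, 2, 5, 0, 1, 9, 0, 0, 3, 1]
        ms = np.linspace(0.05, 6.0, 120)
        ll = np.array([log_likelihood(m, counts) for m in ms])
        peak = int(np.argmax(ll))
        assert np.all(np.diff(ll[: peak + 1]) > -1e-9)
        assert np.all(np.diff(ll[peak:]) < 1e-9)

    def test_median_recovery_in_simulation(self):
        estimates = []
        for rep in range(60):
            counts = simulate_fluctuation(
                FluctuationSimConfig(m_true=2.0, n_cultures=15, seed=5000 + rep)
            )
            estimates.append(mle_m(counts)[0])
        assert abs(np.median(estimates) - 2.0) / 2.0 < 0.15


class TestProfileCi:
    def test_interval_contains_mle(self):
        counts = [0, 1, 0, 4, 22, 0, 2, 1, 0, 3, 0, 1, 7, 0, 0]
        m_hat, _ = mle_m(counts)
        lo, hi = profile_ci(counts)
        assert lo <= m_hat <= hi

    def test_all_zero_closed_form(self):
        # loglik = -C m, so the upper bound solves 2 C m = chi2 quantile
        C = 20
        lo, hi = profile_ci([0] * C)
        assert lo == 0.0
        assert hi == pytest.approx(chi2.ppf(0.95, 1) / (2 * C), rel=1e-6)

    def test_deficit_at_bounds_equals_chi2_quantile(self):
        counts = [0, 3, 1, 0, 0, 11, 2, 0, 1, 5, 0, 0, 2, 1, 0]
        m_hat, ll_hat = mle_m(counts)
        q = chi2.ppf(0.95, 1)
        lo, hi = profile_ci(counts)
        for bound in (lo, hi):
            assert 2 * (ll_hat - log_likelihood(bound, counts)) == pytest.approx(q, abs=1e-5)

    def test_width_shrinks_with_more_cultures(self):
        widths = []
        for n_cultures in (15, 60):
            per_run = []
            for rep in range(25):
                counts = simulate_fluctuation(
                    FluctuationSimConfig(m_true=2.0, n_cultures=n_cultures, seed=9000 + rep)
                )
                lo, hi = profile_ci(counts)
                per_run.append(hi - lo)
            widths.append(np.median(per_run))
        assert widths[1] < widths[0]
        assert widths[1] < 0.7 * widths[0]  # roughly halves at 4x cultures


class TestRatesAndComparison:
    def test_rate_scaling(self):
        est = loh_rate(2.0, (1.0, 3.5), n_final=1e8)
        assert est.rate == pytest.approx(2e-8)
        assert est.ci_low == pytest.approx(1e-8)
        assert est.ci_high == pytest.approx(3.5e-8)

    def test_ci_scales_with_inverse_population(self):
        a = loh_rate(2.0, (1.0, 3.5), n_final=1e8)
        b = loh_rate(2.0, (1.0, 3.5), n_final=1e9)
        assert a.ci_low / b.ci_low == pytest.approx(10.0)

    def test_fold_change_arithmetic(self):
        t = loh_rate(3.0, (2.0, 4.0), n_final=1e6, strain_id="mut")
        r = loh_rate(0.1, (0.05, 0.15), n_final=1e6, strain_id="wt")
        cmp_res = compare_to_reference(t, r)
        assert cmp_res.fold_change == pytest.approx(30.0)
        assert cmp_res.significant  # CIs [2,4]e-6 vs [0.5,1.5]e-7 disjoint

    def test_identical_estimates_not_significant(self):
        est = loh_rate(2.0, (1.0, 3.0), n_final=1e8, strain_id="x")
        cmp_res = compare_to_reference(est, est)
        assert cmp_res.fold_change == pytest.approx(1.0)
        assert not cmp_res.significant

    def test_zero_reference_rate_flagged(self):
        t = loh_rate(1.0, (0.5, 2.0), n_final=1e8)
        r = loh_rate(0.0, (0.0, 0.1), n_final=1e8)
        with pytest.warns(UserWarning):
            cmp_res = compare_to_reference(t, r)
        assert not cmp_res.fold_defined

    def test_estimate_rate_end_to_end(self):
        counts = simulate_fluctuation(FluctuationSimConfig(m_true=2.0, n_cultures=15, seed=2))
        exp = FluctuationExperiment("sim", tuple(int(c) for c in counts), 1e8)
        est = estimate_rate(exp)
        assert est.ci_low <= est.rate <= est.ci_high
        assert est.rate == pytest.approx(est.m_hat / 1e8)


class TestSelectCultures:
    def test_exactly_fifteen_eligible(self):
        readings = [0.3] * 9 + [1.0 + 0.01 * i for i in range(15)]
        assert select_cultures(readings) == list(range(9, 24))

    def test_all_equal_keeps_first_by_input_order(self):
        assert select_cultures([1.0] * 20) == list(range(15))

    def test_shortfall_is_error(self):
        with pytest.raises(ValueError, match="short by"):
            select_cultures([0.4] * 20)

    def test_matches_exhaustive_subset_oracle(self):
        # 4 ineligible + 20 eligible readings; best 15-subset by total
        # deviation from the median, checked against all C(20,15) subsets
        readings = [0.2, 0.4, 0.1, 0.45] + [round(0.6 + 0.1 * i, 2) for i in range(20)]
        chosen = select_cultures(readings, n_keep=15, od_min=0.5)
        eligible = [i for i, r in enumerate(readings) if r > 0.5]
        med = float(np.median([readings[i] for i in eligible]))
        dev = {i: abs(readings[i] - med) for i in eligible}
        best = min(
            itertools.combinations(eligible, 15), key=lambda combo: sum(dev[i] for i in combo)
        )
        assert sum(dev[i] for i in chosen) == pytest.approx(sum(dev[i] for i in best))


class TestExperimentValidation:
    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            FluctuationExperiment("x", (), 1e8)

    def test_small_population_warns(self):
        with pytest.warns(UserWarning):
            FluctuationExperiment("x", (5, 100), 50.0)
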