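"""Statistical core vs. independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers_oracles import (
    fisher_two_sided_oracle,
    mannwhitney_permutation_oracle,
    poisson_interval_oracle,
    poisson_two_sided_oracle,
)
from panelburden import (
    PopulationBurden,
    analyze_population,
    estimate_lambda,
    expectation_interval,
    fisher_exact_2x2,
    fisher_rate_comparison,
    mannwhitney_burden,
    meta_pooled,
    pool_burdens,
    poisson_two_sided,
)
from panelburden.io_formats import DataError


def burden(label, M, L, m, l):
    return PopulationBurden(
        label, [f"{label}{i}" for i in range(len(M))], np.array(M), np.array(L),
        np.array(m), np.array(l),
    )


# ---------------------------------------------------------------------------
# lambda estimation
# ---------------------------------------------------------------------------

class TestEstimateLambda:
    def test_simple_ratio(self):
        assert estimate_lambda(burden("A", [10], [10**6], [0], [10])) == 1e-5

    def test_pooled_ratio_not_mean_of_ratios(self):
        pb = burden("A", [5, 5], [10**6, 3 * 10**6], [0, 0], [1, 1])
        pooled = estimate_lambda(pb)
        mean_of_ratios = np.mean([5 / 10**6, 5 / (3 * 10**6)])
        assert pooled == 10 / (4 * 10**6)
        assert pooled != pytest.approx(mean_of_ratios)

    def test_zero_counts_give_zero_rate(self):
        assert estimate_lambda(burden("A", [0, 0], [10**6, 10**6], [0, 0], [1, 1])) == 0.0

    def test_zero_exposure_is_an_error(self):
        with pytest.raises(DataError):
            estimate_lambda(burden("A", [0], [0], [0], [1]))


# ---------------------------------------------------------------------------
# Exact Poisson test
# ---------------------------------------------------------------------------

class TestPoissonTwoSided:
    def test_degenerate_null(self):
        assert poisson_two_sided(0, 1.0, 0.0) == 1.0

    def test_at_the_mean_all_outcomes_qualify(self):
        assert poisson_two_sided(5, 1.0, 5.0) == 1.0

    def test_frozen_reference_value(self):
        # oracle pmf-summation value, also matching R poisson.test(20, 1, 5)
        assert poisson_two_sided(20, 1.0, 5.0) == pytest.approx(
            3.452135820914455e-07, rel=1e-10
        )

    @pytest.mark.parametrize("mu", [0.5, 5.0])
    def test_matches_pmf_summation_oracle(self, mu):
        for x in range(21):
            p = poisson_two_sided(x, 1.0, mu)
            assert p == pytest.approx(poisson_two_sided_oracle(x, mu), rel=1e-10)
            assert 0.0 < p <= 1.0

    def test_rate_and_exposure_enter_as_product(self):
        assert poisson_two_sided(7, 2.0, 1.3) == poisson_two_sided(7, 1.0, 2.6)

    def test_rejects_non_integer_and_bad_inputs(self):
        with pytest.raises(DataError):
            poisson_two_sided(2.5, 1.0, 1.0)
        with pytest.raises(DataError):
            poisson_two_sided(2, 0.0, 1.0)
        with pytest.raises(DataError):
            poisson_two_sided(2, 1.0, -0.1)


class TestExpectationInterval:
    def test_degenerate(self):
        assert expectation_interval(1.0, 0.0) == (0, 0)

    @pytest.mark.parametrize("mu", [0.3, 1.0, 5.0, 20.0, 100.0, 314.15])
    def test_matches_cdf_scan_oracle(self, mu):
        assert expectation_interval(1.0, mu) == poisson_interval_oracle(mu)

    def test_contains_the_mean(self):
        for mu in (2.0, 17.5, 80.0):
            lo, hi = expectation_interval(1.0, mu)
            assert lo <= mu <= hi

    def test_coverage_at_level(self):
        rng = np.random.default_rng(42)
        lo, hi = expectation_interval(1.0, 5.0)
        draws = rng.poisson(5.0, 100_000)
        assert ((draws >= lo) & (draws <= hi)).mean() >= 0.95


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

class TestFisherExact:
    def test_balanced_table_is_one(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_frozen_enumeration_value(self):
        assert fisher_exact_2x2([[10, 100], [2, 100]]) == pytest.approx(
            fisher_two_sided_oracle(10, 100, 2, 100), rel=1e-10
        )

    def test_symmetric_under_row_swap(self):
        assert fisher_exact_2x2([[10, 100], [2, 100]]) == pytest.approx(
            fisher_exact_2x2([[2, 100], [10, 100]]), rel=1e-12
        )

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(st.tuples(*[st.integers(0, 25)] * 4))
    def test_matches_exact_enumeration(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
            fisher_two_sided_oracle(a, b, c, d), rel=1e-10
        )

    def test_rejects_negative_or_fractional_cells(self):
        with pytest.raises(DataError):
            fisher_exact_2x2([[1, -1], [1, 1]])
        with pytest.raises(DataError):
            fisher_exact_2x2([[1.5, 1], [1, 1]])

    def test_rate_comparison_modes(self):
        a = burden("A", [9, 9], [10**6] * 2, [3, 0], [50_000] * 2)
        b = burden("B", [9, 9], [10**6] * 2, [0, 0], [50_000] * 2)
        p_events = fisher_rate_comparison(a, b, mode="events_vs_exposure")
        assert p_events == pytest.approx(
            fisher_exact_2x2([[3, 100_000 - 3], [0, 100_000]]), rel=1e-12
        )
        p_carr = fisher_rate_comparison(a, b, mode="carriers")
        assert p_carr == pytest.approx(fisher_exact_2x2([[1, 1], [0, 2]]), rel=1e-12)
        # symmetry in group order
        assert fisher_rate_comparison(b, a) == pytest.approx(p_events, rel=1e-12)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_identical_multisets_give_one(self):
        assert mannwhitney_burden([1, 1, 2], [1, 1, 2]) == 1.0

    def test_fully_separated_small_groups(self):
        # 2/20 arrangements are as extreme (two-sided)
        assert mannwhitney_burden([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_shift_invariance(self):
        a, b = [0, 1, 1, 3, 2], [2, 2, 0, 4]
        assert mannwhitney_burden(a, b) == pytest.approx(
            mannwhitney_burden([x + 7 for x in a], [x + 7 for x in b])
        )

    def test_symmetry(self):
        a, b = [0, 0, 1, 2, 2, 5], [1, 1, 1, 3]
        assert mannwhitney_burden(a, b) == pytest.approx(mannwhitney_burden(b, a))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        a=st.lists(st.integers(0, 4), min_size=2, max_size=8),
        b=st.lists(st.integers(0, 4), min_size=2, max_size=8),
    )
    def test_small_sample_exact_matches_permutation_enumeration(self, a, b):
        # heavily tied count data, the regime the exact branch exists for
        assert mannwhitney_burden(a, b) == pytest.approx(
            mannwhitney_permutation_oracle(a, b), rel=1e-10
        )

    def test_large_samples_use_tie_corrected_normal_approximation(self):
        rng = np.random.default_rng(3)
        a = rng.poisson(3.0, 40)
        b = rng.poisson(4.0, 40)
        p = mannwhitney_burden(a, b)
        assert 0.0 < p <= 1.0


# ---------------------------------------------------------------------------
# Pooled meta-analysis
# ---------------------------------------------------------------------------

class TestMetaPooled:
    def cohort_pair(self):
        c1 = burden("White", [9, 12], [10**6, 10**6], [2, 1], [40_000, 41_000])
        c2 = burden("White", [8, 11], [9 * 10**5, 10**6], [1, 2], [39_000, 42_000])
        return c1, c2

    def test_duplicated_cohort_preserves_lambda(self):
        c1, _ = self.cohort_pair()
        pooled = pool_burdens([c1, c1])
        assert estimate_lambda(pooled) == pytest.approx(estimate_lambda(c1), rel=1e-12)

    def test_pooling_one_cohort_is_identity(self):
        c1, _ = self.cohort_pair()
        assert meta_pooled([c1], test="poisson") == pytest.approx(
            poisson_two_sided(c1.sum_m, c1.sum_l, estimate_lambda(c1)), rel=1e-12
        )

    def test_pooled_counts_are_sums(self):
        c1, c2 = self.cohort_pair()
        pooled = pool_burdens([c1, c2])
        assert pooled.sum_m == c1.sum_m + c2.sum_m
        assert pooled.sum_L == c1.sum_L + c2.sum_L
        assert pooled.n_samples == 4

    def test_power_grows_with_exposure_when_enriched(self):
        # doubled (x, T) at an enriched rate: evidence accumulates, p shrinks
        lam = 1e-5
        p1 = poisson_two_sided(30, 10**6, lam)  # x/T = 3e-5 > lam
        p2 = poisson_two_sided(60, 2 * 10**6, lam)
        assert p2 < p1

    def test_fisher_meta_needs_comparison_group(self):
        c1, c2 = self.cohort_pair()
        with pytest.raises(DataError):
            meta_pooled([c1, c2], test="fisher")

    def test_cannot_pool_different_populations(self):
        c1, _ = self.cohort_pair()
        other = burden("Black", [5], [10**6], [0], [40_000])
        with pytest.raises(DataError):
            pool_burdens([c1, other])


class TestAnalyzePopulation:
    def test_fields_are_mutually_consistent(self):
        pb = burden("White", [9, 12, 8, 10, 7], [10**6] * 5, [2, 1, 0, 1, 0], [40_000] * 5)
        res = analyze_population(pb, cohort="c1")
        lam = estimate_lambda(pb)
        assert res.lambda_hat == lam
        assert res.expected == pytest.approx(lam * pb.sum_l)
        assert res.p_poisson == pytest.approx(
            poisson_two_sided(pb.sum_m, pb.sum_l, lam), rel=1e-12
        )
        lo, hi = res.expectation_interval
        assert lo <= res.expected <= hi or res.expected < 1
        assert not res.small_sample

    def test_small_population_is_flagged(self):
        pb = burden("Asian", [3, 4], [10**6] * 2, [0, 0], [40_000] * 2)
        assert analyze_population(pb).small_sample
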