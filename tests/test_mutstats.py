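"""Statistical battery vs independent enumeration/CDF-inversion oracles."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy import stats as sps

from mtduplex.mutstats import (
    adjust_fdr,
    chi2_montecarlo,
    fisher_compare,
    mutation_frequency,
    observed_expected_binomial,
    permutation_median_test,
    poisson_ci,
    spectrum_table,
    strand_bias_table,
    titv_ratio,
)


class TestFrequency:
    def test_printed_worked_example(self):
        # 465 events over 1,061,353,310 sequenced bases
        assert mutation_frequency(465, 1_061_353_310, 1.0) == pytest.approx(4.381e-7, rel=1e-3)

    def test_zero_events_zero_frequency(self):
        assert mutation_frequency(0, 1e9, 1.0) == 0.0

    def test_doubling_denominator_halves_frequency(self):
        f1 = mutation_frequency(10, 1e6, 2.0)
        f2 = mutation_frequency(10, 1e6, 4.0)
        assert f1 == pytest.approx(2 * f2)

    def test_invalid_denominator_raises(self):
        with pytest.raises(ValueError):
            mutation_frequency(1, 0.0, 0.0)


class TestPoissonCI:
    @staticmethod
    def oracle(count, level=0.95):
        """CDF-inversion oracle: root-find the Garwood bounds directly."""
        alpha = 1 - level
        lo = 0.0
        if count > 0:
            lo = optimize.brentq(
                lambda mu: sps.poisson.sf(count - 1, mu) - alpha / 2, 1e-12, 10 * count + 10
            )
        hi = optimize.brentq(
            lambda mu: sps.poisson.cdf(count, mu) - alpha / 2, 1e-12, 10 * count + 50
        )
        return lo, hi

    def test_zero_count_lower_bound_is_zero(self):
        lo, hi = poisson_ci(0, 1.0)
        assert lo == 0.0 and hi > 0

    @pytest.mark.parametrize("count", [1, 5, 100, 465])
    def test_matches_cdf_inversion_oracle(self, count):
        lo, hi = poisson_ci(count, 1.0)
        olo, ohi = self.oracle(count)
        assert lo == pytest.approx(olo, rel=1e-6)
        assert hi == pytest.approx(ohi, rel=1e-6)

    def test_relative_width_shrinks_with_count(self):
        widths = []
        for count, denom in [(10, 1e6), (100, 1e7), (1000, 1e8)]:
            lo, hi = poisson_ci(count, denom)
            widths.append((hi - lo) / (count / denom))
        assert widths[0] > widths[1] > widths[2]

    def test_interval_contains_point_estimate(self):
        for count in (1, 7, 50):
            lo, hi = poisson_ci(count, 100.0)
            assert lo <= count / 100.0 <= hi


class TestFisher:
    def test_symmetric_table_gives_p_one(self):
        fold, odds, p = fisher_compare(5, 10, 5, 10)
        assert p == 1.0 and odds == 1.0 and fold == 1.0

    def test_matches_hypergeometric_enumeration(self, rng):
        """Exact two-sided p equals direct enumeration over the margin."""
        for _ in range(25):
            n1, n2 = int(rng.integers(0, 9)), int(rng.integers(0, 9))
            d1, d2 = n1 + int(rng.integers(1, 15)), n2 + int(rng.integers(1, 15))
            _, _, p = fisher_compare(n1, d1, n2, d2)
            # enumeration oracle: all tables with the same margins
            k_total = n1 + n2
            prob = lambda k: comb(d1, k) * comb(d2, k_total - k) / comb(d1 + d2, k_total)
            p_obs = prob(n1)
            p_oracle = sum(
                prob(k)
                for k in range(max(0, k_total - d2), min(d1, k_total) + 1)
                if prob(k) <= p_obs * (1 + 1e-9)
            )
            assert p == pytest.approx(p_oracle, rel=1e-9)

    def test_fold_change_reported(self):
        fold, _, _ = fisher_compare(20, 100, 5, 100)
        assert fold == pytest.approx(4.0)


class TestBinomialObsExp:
    def test_matches_direct_tail_summation(self):
        p = 877 / 16300
        got = observed_expected_binomial(10, 50, 877, 16300, "greater")
        oracle = sum(comb(50, k) * p**k * (1 - p) ** (50 - k) for k in range(10, 51))
        assert got == pytest.approx(oracle, rel=1e-12)

    def test_zero_observed_with_greater_is_one(self):
        assert observed_expected_binomial(0, 50, 877, 16300, "greater") == 1.0

    def test_expected_proportion_two_sided_near_one(self):
        # 10 of 100 in a region covering 10% of the genome
        p = observed_expected_binomial(10, 100, 1630, 16300, "two-sided")
        assert p > 0.99

    def test_region_larger_than_genome_rejected(self):
        with pytest.raises(ValueError):
            observed_expected_binomial(1, 10, 20000, 16300)


class TestPermutation:
    def test_identical_groups_never_significant(self, rng):
        # constant data: every relabelling reproduces the statistic
        p = permutation_median_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0], n_perm=1000, rng=rng)
        assert p == 1.0
        # same values in both groups: null-central, far from significance
        vals = [1.0, 2.0, 3.0, 4.0]
        p2 = permutation_median_test(vals, vals, n_perm=1000, rng=rng)
        assert p2 >= 0.5

    def test_exhaustive_matches_manual_enumeration(self):
        a, b = [3.0, 5.0], [1.0, 2.0]
        p = permutation_median_test(a, b, n_perm=10_000)
        pooled = a + b
        observed = np.median(a) - np.median(b)
        hits = 0
        for pick in combinations(range(4), 2):
            pa = [pooled[i] for i in pick]
            pb = [pooled[i] for i in range(4) if i not in pick]
            hits += (np.median(pa) - np.median(pb)) >= observed - 1e-12
        assert p == pytest.approx(hits / 6)

    def test_one_sided_orientation(self, rng):
        a = [10.0, 11.0, 12.0, 13.0]
        b = [1.0, 2.0, 3.0, 4.0]
        p_a = permutation_median_test(a, b, alternative="a_greater", rng=rng)
        p_b = permutation_median_test(a, b, alternative="b_greater", rng=rng)
        assert p_a < 0.05
        assert p_b == 1.0

    def test_monte_carlo_agrees_with_exhaustive_within_error(self, rng):
        a = list(rng.normal(0.5, 1, 6))
        b = list(rng.normal(0.0, 1, 6))
        p_ex = permutation_median_test(a, b, n_perm=comb(12, 6) + 1)
        n_mc = 20_000
        p_mc = permutation_median_test(a, b, n_perm=n_mc, rng=rng)
        se = np.sqrt(p_ex * (1 - p_ex) / n_mc)
        assert abs(p_mc - p_ex) < 3 * se + 1 / n_mc

    def test_empty_group_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_median_test([], [1.0], rng=rng)


class TestFdr:
    def test_benjamini_yekutieli_worked_values(self):
        # m=3, c(3)=11/6: all three adjust to 5.5 * 0.01 = 0.055
        adj = adjust_fdr([0.01, 0.02, 0.03], method="BY")
        assert adj == pytest.approx([0.055, 0.055, 0.055])

    def test_single_p_unchanged_under_bh(self):
        assert adjust_fdr([0.035], method="BH") == pytest.approx([0.035])

    def test_adjusted_values_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=20)
        adj = adjust_fdr(p, method="BY")
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])


class TestSpectrum:
    @staticmethod
    def records(counts):
        rows = []
        for t, n in counts.items():
            ref, alt = t.split(">")
            for _ in range(n):
                rows.append({"mutation_type": t, "ref": ref, "alt": alt, "n_events": 1})
        return pd.DataFrame(rows)

    def test_titv_of_known_mix(self):
        rec = self.records({"G>A": 5, "C>T": 3, "G>T": 1, "A>C": 1})
        assert titv_ratio(rec) == pytest.approx(4.0)

    def test_type_specific_denominators(self):
        nt = {"A": 100.0, "C": 200.0, "G": 300.0, "T": 400.0}
        spec = spectrum_table(self.records({"C>T": 4}), nt).set_index("mutation_type")
        assert spec.loc["C>T", "denominator_bp"] == 200.0
        assert spec.loc["C>T", "frequency"] == pytest.approx(0.02)
        assert spec.loc["G>A", "n_mutations"] == 0

    def test_strand_collapse_label(self):
        spec = spectrum_table(self.records({"G>T": 1}), {b: 10.0 for b in "ACGT"})
        row = spec.set_index("mutation_type").loc["G>T"]
        assert row["collapsed_type"] == "C>A"

    def test_strand_bias_recovers_planted_excess(self):
        # 50 G>A vs 10 C>T with equal base content -> odds ratio ~ 5
        nt = {b: 1e6 for b in "ACGT"}
        tbl = strand_bias_table(self.records({"G>A": 50, "C>T": 10}), nt)
        row = tbl.set_index("type_1").loc["C>T"]
        assert row["fold_1_over_2"] == pytest.approx(0.2, rel=1e-6)
        assert row["odds_ratio"] == pytest.approx(0.2, rel=0.01)
        assert row["p_value"] < 1e-5

    def test_balanced_reciprocals_show_no_bias(self):
        nt = {b: 1e6 for b in "ACGT"}
        tbl = strand_bias_table(self.records({"G>A": 20, "C>T": 20}), nt)
        row = tbl.set_index("type_1").loc["C>T"]
        assert row["p_value"] == 1.0


class TestChi2MonteCarlo:
    def test_identical_spectra_not_rejected(self, rng):
        counts = [30, 20, 10, 5]
        p = chi2_montecarlo(counts, counts, n_sim=500, rng=rng)
        assert p == 1.0

    def test_grossly_different_spectra_rejected(self, rng):
        p = chi2_montecarlo([100, 5, 5, 5], [5, 5, 5, 100], n_sim=500, rng=rng)
        assert p < 0.01
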