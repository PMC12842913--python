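"""Rating tallies, exact binomial intervals and cohort summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from ldctqa.cohort import exact_binomial_ci, summarize_cohort, tally_ratings


def ratings_from_counts(counts):
    """Expand counts ordered Perfect(6)..Insufficient(1) into a rating list."""
    out = []
    for rating, c in zip(range(6, 0, -1), counts):
        out.extend([rating] * c)
    return out


class TestTallyRatings:
    def test_reader_study_lung_counts(self):
        tally = tally_ratings(ratings_from_counts([16, 73, 8, 1, 0, 0]))
        assert tally.n == 98
        rounded = [round(p, 1) for p in tally.cumulative_percent]
        assert rounded == [16.3, 90.8, 99.0, 100.0, 100.0, 100.0]

    def test_reader_study_aorta_counts(self):
        tally = tally_ratings(ratings_from_counts([69, 26, 3, 0, 0, 0]))
        rounded = [round(p, 1) for p in tally.cumulative_percent]
        assert rounded == [70.4, 96.9, 100.0, 100.0, 100.0, 100.0]

    def test_all_perfect_is_hundred_everywhere(self):
        tally = tally_ratings([6] * 12)
        assert all(p == 100.0 for p in tally.cumulative_percent)

    def test_cumulative_is_nondecreasing_toward_worse_labels(self):
        tally = tally_ratings([6, 5, 5, 4, 3, 2, 1, 1])
        assert list(tally.cumulative_percent) == sorted(tally.cumulative_percent)
        assert tally.cumulative_percent[-1] == 100.0

    def test_out_of_range_rating_rejected(self):
        with pytest.raises(ValueError):
            tally_ratings([6, 7])
        with pytest.raises(ValueError):
            tally_ratings([0, 3])

    def test_formatted_rows_use_one_decimal(self):
        tally = tally_ratings(ratings_from_counts([16, 73, 8, 1, 0, 0]))
        row = tally.formatted_rows()[1]
        assert row.startswith("Nearly Perfect\t73\t90.8%")
        assert "[CI: 83.3-95.7%]" in row

    @given(st.lists(st.integers(1, 6), min_size=1, max_size=40),
           st.randoms(use_true_random=False))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariant_under_permutation(self, ratings, rnd):
        shuffled = list(ratings)
        rnd.shuffle(shuffled)
        a, b = tally_ratings(ratings), tally_ratings(shuffled)
        assert a.counts == b.counts
        assert a.cumulative_percent == b.cumulative_percent


class TestExactBinomialCI:
    def test_all_successes_lower_bound_closed_form(self):
        lo, hi = exact_binomial_ci(98, 98)
        assert hi == 1.0
        assert lo == pytest.approx(0.025 ** (1 / 98))
        assert round(lo * 100, 1) == 96.3

    def test_zero_successes_upper_bound_closed_form(self):
        lo, hi = exact_binomial_ci(0, 98)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 98))

    def test_interval_matches_printed_reader_study_values(self):
        lo, hi = exact_binomial_ci(89, 98)
        assert (round(lo * 100, 1), round(hi * 100, 1)) == (83.3, 95.7)

    @pytest.mark.parametrize("k,n", [(-1, 10), (11, 10), (0, 0)])
    def test_invalid_inputs_rejected(self, k, n):
        with pytest.raises(ValueError):
            exact_binomial_ci(k, n)

    def test_agrees_with_binomial_tail_bisection(self):
        # independent oracle: invert the binomial tail sums by bisection
        def bisect(fn, lo, hi, iters=60):
            for _ in range(iters):
                mid = 0.5 * (lo + hi)
                if fn(mid):
                    lo = mid
                else:
                    hi = mid
            return 0.5 * (lo + hi)

        for n in range(1, 21):
            for k in range(n + 1):
                lo, hi = exact_binomial_ci(k, n)
                if k > 0:
                    oracle_lo = bisect(lambda p: binom.sf(k - 1, n, p) < 0.025, 0.0, 1.0)
                    assert lo == pytest.approx(oracle_lo, abs=1e-6)
                if k < n:
                    oracle_hi = bisect(lambda p: binom.cdf(k, n, p) > 0.025, 0.0, 1.0)
                    assert hi == pytest.approx(oracle_hi, abs=1e-6)


class TestSummarizeCohort:
    @staticmethod
    def record(caudal=10.0, cranial=5.0, us_c=False, us_cr=False,
               sigma=30.0, frac=0.1):
        return dict(caudal_overscan_mm=caudal, cranial_overscan_mm=cranial,
                    underscan_caudal=us_c, underscan_cranial=us_cr,
                    sigma_norm=sigma, fraction_nonlung_slices=frac)

    def test_underscan_rates_match_count_arithmetic(self):
        n, n_caudal, n_cranial = 38_834, 1694, 347
        records = []
        for i in range(n):
            records.append(self.record(us_c=i < n_caudal, us_cr=i < n_cranial,
                                       caudal=0.0 if i < n_caudal else 10.0,
                                       cranial=0.0 if i < n_cranial else 5.0))
        s = summarize_cohort(records)
        assert round(100 * s.underscan_caudal_rate, 2) == 4.36
        assert round(100 * s.underscan_cranial_rate, 2) == 0.89

    def test_conditional_overscan_statistics(self):
        records = [self.record(caudal=10.0)] * 5 + [self.record(caudal=0.0, us_c=True)] * 5
        s = summarize_cohort(records)
        assert s.caudal_overscan_mean_mm == pytest.approx(10.0)
        assert s.caudal_overscan_sd_mm == pytest.approx(0.0)
        assert s.n_caudal_overscanned == 5

    def test_missing_noise_excluded_and_counted(self):
        records = [self.record(sigma=20.0), self.record(sigma=40.0),
                   self.record(sigma=None)]
        s = summarize_cohort(records)
        assert s.sigma_norm_mean == pytest.approx(30.0)
        assert s.n_noise_excluded == 1

    def test_both_underscan_rate(self):
        records = [self.record(us_c=True, us_cr=True, caudal=0.0, cranial=0.0),
                   self.record(us_c=True, caudal=0.0), self.record()]
        s = summarize_cohort(records)
        assert s.underscan_both_rate == pytest.approx(1 / 3)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([])
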