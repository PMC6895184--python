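import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from uvvisdb import valstats
from uvvisdb.valstats import (
    EmptySampleError,
    Histogram,
    build_histogram,
    epsilon_flags,
    epsilon_from_oscillator,
    histogram_intersection,
    mae,
    quartile_summary,
    regression_with_ci,
    solvent_tally,
    spearman_corr,
    subsample_stability,
    summary_stats,
)


class TestHistogram:
    def test_half_open_convention(self):
        h = build_histogram([5, 11.9, 12], origin=0, bin_width=12)
        assert h.counts == [2, 1]
        assert h.n_total == 3

    def test_single_value(self):
        h = build_histogram([7.0], origin=0, bin_width=12)
        assert h.counts == [1]

    def test_empty(self):
        h = build_histogram([], origin=0, bin_width=12)
        assert h.counts == [] and h.n_total == 0

    def test_below_origin_rejected(self):
        with pytest.raises(ValueError):
            build_histogram([-1.0], origin=0, bin_width=12)

    def test_uniform_binomial_oracle(self):
        rng = np.random.default_rng(2024)
        values = rng.uniform(0, 120, size=10_000)
        h = build_histogram(values, origin=0, bin_width=12)
        assert len(h.counts) == 10
        # each bin count ~ Binomial(1e4, 0.1): 5 sigma around the mean
        sigma = math.sqrt(10_000 * 0.1 * 0.9)
        for count in h.counts:
            assert abs(count - 1000) < 5 * sigma


class TestIntersection:
    def test_identical(self):
        h = build_histogram([1, 2, 3, 15, 26], origin=0, bin_width=12)
        assert histogram_intersection(h, h) == pytest.approx(1.0)

    def test_disjoint(self):
        h1 = build_histogram([1, 2], origin=0, bin_width=12)
        h2 = build_histogram([25, 30], origin=0, bin_width=12)
        assert histogram_intersection(h1, h2) == 0.0

    def test_half_overlap(self):
        h1 = Histogram(origin=0, bin_width=1, counts=[1, 1, 0], n_total=2)
        h2 = Histogram(origin=0, bin_width=1, counts=[0, 1, 1], n_total=2)
        assert histogram_intersection(h1, h2) == pytest.approx(0.5)

    def test_empty_undefined(self):
        h = build_histogram([1.0], origin=0, bin_width=12)
        empty = build_histogram([], origin=0, bin_width=12)
        with pytest.raises(EmptySampleError):
            histogram_intersection(h, empty)

    def test_mismatched_bins(self):
        h1 = build_histogram([1.0], origin=0, bin_width=12)
        h2 = build_histogram([1.0], origin=0, bin_width=6)
        with pytest.raises(ValueError):
            histogram_intersection(h1, h2)

    @given(
        st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=12),
        st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=12),
    )
    @settings(max_examples=200)
    def test_brute_force_and_symmetry(self, c1, c2):
        n1, n2 = sum(c1), sum(c2)
        if n1 == 0 or n2 == 0:
            return
        h1 = Histogram(origin=0, bin_width=1, counts=c1, n_total=n1)
        h2 = Histogram(origin=0, bin_width=1, counts=c2, n_total=n2)
        # brute force: explicit loop over padded proportions
        k = max(len(c1), len(c2))
        p1 = [c / n1 for c in c1] + [0.0] * (k - len(c1))
        p2 = [c / n2 for c in c2] + [0.0] * (k - len(c2))
        expected = sum(min(a, b) for a, b in zip(p1, p2))
        assert histogram_intersection(h1, h2) == pytest.approx(expected)
        assert histogram_intersection(h2, h1) == pytest.approx(
            histogram_intersection(h1, h2)
        )
        assert 0.0 <= histogram_intersection(h1, h2) <= 1.0 + 1e-12


class TestSummaryStats:
    def test_symmetric(self):
        s = summary_stats([1.0, 2.0, 3.0])
        assert s.skew == pytest.approx(0.0)
        assert s.median == 2.0

    def test_positive_skew_sign(self):
        assert summary_stats([0.0, 0.0, 0.0, 10.0]).skew > 0

    def test_n_too_small(self):
        with pytest.raises(EmptySampleError):
            summary_stats([1.0])

    def test_lognormal_closed_form(self):
        sigma = 0.5
        rng = np.random.default_rng(3)
        values = rng.lognormal(mean=1.0, sigma=sigma, size=10_000)
        w = math.exp(sigma**2)
        expected = (w + 2) * math.sqrt(w - 1)
        assert summary_stats(values).skew == pytest.approx(expected, rel=0.10)


class TestSubsampleStability:
    def test_fraction_one_identity(self):
        values = list(range(100))
        table = subsample_stability(values, [1.0], seed=3)
        assert table[1.0] == summary_stats(values)

    def test_deterministic(self):
        values = np.random.default_rng(0).normal(size=500).tolist()
        a = subsample_stability(values, [0.25, 0.5], seed=7)
        b = subsample_stability(values, [0.25, 0.5], seed=7)
        assert a == b

    def test_too_small_fraction(self):
        with pytest.raises(EmptySampleError):
            subsample_stability([1.0, 2.0, 3.0], [0.25], seed=0)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            subsample_stability(list(range(10)), [1.5], seed=0)


class TestEpsilonFlags:
    def test_out_of_range_boundary(self):
        flags = epsilon_flags([5e5 + 1, 2e4])
        assert flags.flags[0] == "out_of_range"
        assert flags.flags[1] == "ok"

    def test_inclusive_range_bounds(self):
        flags = epsilon_flags([1e3, 5e5])
        assert "out_of_range" not in flags.flags

    def test_equal_values_unflagged(self):
        flags = epsilon_flags([2e4] * 10)
        assert all(f == "ok" for f in flags.flags)

    def test_percentile_partition_within_one_rank(self):
        values = np.linspace(2e3, 4e5, 1000).tolist()
        flags = epsilon_flags(values)
        n_low = flags.flags.count("low_percentile")
        n_high = flags.flags.count("high_percentile")
        assert abs(n_low - 200) <= 1
        assert abs(n_high - 100) <= 1

    def test_out_of_range_excluded_from_percentiles(self):
        values = [1.0] * 50 + np.linspace(1e4, 1e5, 100).tolist()
        flags = epsilon_flags(values)
        # the 50 tiny values are out_of_range, not low_percentile
        assert flags.flags[:50] == ["out_of_range"] * 50
        assert flags.flags[50:].count("low_percentile") == 20


class TestEpsilonFromOscillator:
    def test_zero(self):
        assert epsilon_from_oscillator(0.0, 1.0) == 0.0

    def test_unit_substitution(self):
        assert epsilon_from_oscillator(1.0, 1.0) == pytest.approx(2.699e4)

    def test_inverse_substitution(self):
        assert epsilon_from_oscillator(0.5, 2.699e4) == pytest.approx(0.5)

    def test_invalid_b(self):
        with pytest.raises(ValueError):
            epsilon_from_oscillator(1.0, 0.0)

    @given(
        # bounded away from the subnormal range, where exact power-of-two
        # scaling genuinely breaks down
        st.floats(min_value=1e-12, max_value=10),
        st.floats(min_value=1e-3, max_value=1e6),
    )
    def test_scaling_laws_machine_precision(self, f, b):
        assert epsilon_from_oscillator(2 * f, b) == 2 * epsilon_from_oscillator(f, b)
        assert epsilon_from_oscillator(f, 2 * b) == epsilon_from_oscillator(f, b) / 2
        assert epsilon_from_oscillator(0.0, b) == 0.0


class TestMae:
    def test_identical(self):
        assert mae([1, 2, 3], [1, 2, 3]) == 0.0

    def test_constant_shift(self):
        obs = [10.0, 20.0, 30.0]
        assert mae([v + 7.5 for v in obs], obs) == pytest.approx(7.5)

    def test_empty(self):
        with pytest.raises(EmptySampleError):
            mae([], [])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mae([1.0], [1.0, 2.0])

    def test_folded_normal_oracle(self):
        mu, sigma, n = 50.0, 10.0, 10_000
        rng = np.random.default_rng(123)
        obs = rng.uniform(300, 700, size=n)
        pred = obs + mu + rng.normal(0, sigma, size=n)
        expected = valstats._folded_normal_mean(mu, sigma)
        se = sigma / math.sqrt(n)
        assert abs(mae(pred, obs) - expected) < 3 * se


class TestRegression:
    def test_perfect_fit(self):
        x = np.arange(10.0)
        res = regression_with_ci(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert np.allclose(res.mean_upper - res.mean_lower, 0.0, atol=1e-8)

    def test_null_case(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, size=5000)
        y = rng.normal(size=5000)
        assert abs(regression_with_ci(x, y).r_squared) < 0.01

    def test_degenerate_x(self):
        with pytest.raises(ValueError):
            regression_with_ci([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_coverage_simulation(self):
        """~98% of true mean-response points fall inside the band."""
        x = np.linspace(0, 1, 25)
        truth = 3.0 * x - 1.0
        # the band is pointwise, so check average pointwise coverage
        rng = np.random.default_rng(18)
        inside = 0
        n_pts = 0
        for _ in range(400):
            y = truth + rng.normal(0, 0.5, size=x.size)
            res = regression_with_ci(x, y, conf=0.98)
            inside += int(np.sum((res.mean_lower <= truth) & (truth <= res.mean_upper)))
            n_pts += x.size
        coverage = inside / n_pts
        assert 0.96 <= coverage <= 1.0


class TestQuartiles:
    def test_linear_interpolation_oracle(self):
        q = quartile_summary(list(range(1, 101)))
        assert q.median == 50.5
        assert q.lower_quartile == pytest.approx(25.75)
        assert q.upper_quartile == pytest.approx(75.25)

    def test_all_equal(self):
        q = quartile_summary([5.0] * 8)
        assert q.upper_quartile - q.lower_quartile == 0.0
        assert q.outliers == []

    def test_single_outlier(self):
        values = [1.0, 2.0, 3.0, 4.0, 5.0, 100.0]
        q = quartile_summary(values)
        assert q.outliers == [100.0]
        assert q.whisker_high == 5.0

    def test_too_small(self):
        with pytest.raises(EmptySampleError):
            quartile_summary([1.0, 2.0, 3.0])


class TestSpearman:
    def test_monotone(self):
        x = [1, 2, 3, 4, 5]
        assert spearman_corr(x, [math.exp(v) for v in x]) == pytest.approx(1.0)

    def test_reversed(self):
        x = [1, 2, 3, 4, 5]
        assert spearman_corr(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_brute_force_rank_formula(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0, 9.0]
        y = [2.0, 7.0, 1.0, 8.0, 3.0, 0.5]
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]  # Pearson on ranks
        assert spearman_corr(x, y) == pytest.approx(float(expected))

    def test_zero_rank_variance(self):
        with pytest.raises(ValueError):
            spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSolventTally:
    def test_alias_merging(self, record_factory):
        recs = [
            record_factory(key="AAAAAAAAAAAAAA-AAAAAAAAAA-N", solvent="EtOH"),
            record_factory(key="BBBBBBBBBBBBBB-BBBBBBBBBB-N", solvent="ethanol"),
            record_factory(key="CCCCCCCCCCCCCC-CCCCCCCCCC-N", solvent="Ethanol"),
        ]
        tally = solvent_tally(recs, min_count=1)
        assert tally.entries == [("ethanol", 3, 24.5)]

    def test_per_compound_single_count(self, record_factory):
        rec = record_factory(solvent="ethanol")
        rec.uvvis.append(
            type(rec.uvvis[0])(doi="10.1/other", peaks=[], solvent="EtOH")
        )
        tally = solvent_tally([rec], min_count=1)
        assert tally.entries[0][1] == 1

    def test_dielectric_ordering(self, record_factory):
        solvents = ["DMSO", "toluene", "acetonitrile", "chloroform", "THF",
                    "DCM", "acetone", "ethanol", "methanol", "DMF"]
        recs = [
            record_factory(key=f"{chr(65 + i) * 14}-{chr(65 + i) * 10}-N", solvent=s)
            for i, s in enumerate(solvents)
        ]
        tally = solvent_tally(recs, min_count=1)
        names = [name for name, _, _ in tally.entries]
        assert names == [
            "toluene", "chloroform", "tetrahydrofuran", "dichloromethane",
            "acetone", "ethanol", "methanol", "acetonitrile",
            "dimethylformamide", "dimethyl sulfoxide",
        ]
        constants = [eps for _, _, eps in tally.entries]
        assert constants == sorted(constants)

    def test_unknown_routed_to_unrecognized(self, record_factory):
        tally = solvent_tally([record_factory(solvent="unobtainium")], min_count=1)
        assert tally.entries == []
        assert tally.unrecognized == {"unobtainium": 1}

    def test_threshold(self, record_factory):
        recs = [
            record_factory(key=f"{chr(65 + i % 26) * 14}-{chr(65 + i // 26 % 26) * 10}-N",
                           solvent="ethanol")
            for i in range(5)
        ]
        assert solvent_tally(recs, min_count=100).entries == []
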