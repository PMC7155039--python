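import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endolakes.change import (
    ChangeVector,
    PeriodDefinition,
    change_vector,
    linear_trend,
    percent_change,
    period_summary,
    regional_rollup,
    wilcoxon_rank_sum,
)


class TestPeriodDefinition:
    def test_default_counts(self):
        p = PeriodDefinition.default()
        assert len(p.p1) == 16 and len(p.p2) == 18
        assert 2012 not in p.p2

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            PeriodDefinition(p1=(1999, 2000), p2=(2000, 2001))


class TestPercentChange:
    def test_printed_snowmelt_lake_row(self):
        assert percent_change(700109, 509184) == -27

    def test_printed_monsoonal_wetland_row(self):
        assert percent_change(3216, 3448) == 7

    def test_no_change(self):
        assert percent_change(100, 100) == 0

    def test_half_away_from_zero(self):
        assert percent_change(200, 201) == 1  # 0.5 -> 1
        assert percent_change(200, 199) == -1  # -0.5 -> -1

    def test_zero_baseline_error(self):
        with pytest.raises(ValueError):
            percent_change(0, 5)

    @given(m1=st.floats(1, 1e6), m2=st.floats(0, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_sign_matches_difference(self, m1, m2):
        pct = percent_change(m1, m2)
        if abs(100 * (m2 - m1) / m1) >= 0.5:
            assert np.sign(pct) == np.sign(m2 - m1)


class TestWilcoxon:
    def test_complete_separation_exact(self):
        u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)  # 2 * 1/20 labelings

    def test_identical_tied_samples(self):
        _, p = wilcoxon_rank_sum([1, 1, 1], [1, 1, 1])
        assert p == 1.0

    def test_empty_sample_error(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1, 2])

    def test_exact_requires_no_ties(self):
        with pytest.raises(ValueError, match="tie"):
            wilcoxon_rank_sum([1, 1, 2], [3, 4, 5], method="exact")

    def test_exact_matches_scipy(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(4)
        for _ in range(20):
            x, y = rng.normal(size=6), rng.normal(size=7)
            u, p = wilcoxon_rank_sum(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_approx_close_to_exact_at_n10(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            x, y = rng.normal(size=10), rng.normal(size=10)
            _, pe = wilcoxon_rank_sum(x, y, method="exact")
            _, pa = wilcoxon_rank_sum(x, y, method="asymptotic")
            assert abs(pe - pa) <= 0.02

    def test_large_samples_use_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=16)
        y = rng.normal(1.5, 1, size=18)
        _, p = wilcoxon_rank_sum(x, y)
        assert 0 < p < 0.05


class TestLinearTrend:
    def test_perfect_line(self):
        years = np.arange(1984, 2019)
        res = linear_trend(years, 2 * years + 1)
        assert res.slope == pytest.approx(2)
        assert res.p < 1e-12

    def test_constant_series_degenerate(self):
        res = linear_trend([1, 2, 3, 4], [5, 5, 5, 5])
        assert res.slope == 0 and res.degenerate
        assert np.isnan(res.p)

    def test_identical_years_error(self):
        with pytest.raises(ValueError, match="years"):
            linear_trend([2000, 2000, 2000], [1, 2, 3])

    def test_nan_values_skipped(self):
        years = np.arange(2000, 2010)
        vals = years * 1.0
        vals[3] = np.nan
        res = linear_trend(years, vals)
        assert res.slope == pytest.approx(1.0)

    def test_noisy_slope_recovered_within_3se(self):
        rng = np.random.default_rng(17)
        years = np.arange(34)
        vals = -3.0 * years + rng.normal(0, 1, 34)
        res = linear_trend(years, vals)
        assert abs(res.slope - (-3.0)) < 3 * res.se


class TestPeriodSummary:
    def test_two_level_series(self):
        periods = PeriodDefinition.default()
        years = list(periods.p1) + list(periods.p2)
        values = [10.0] * 16 + [5.0] * 18
        s = period_summary(years, values, periods)
        assert s.change == -5 and s.percent == -50
        assert s.n1 == 16 and s.n2 == 18

    def test_printed_means_reproduce_percent(self):
        periods = PeriodDefinition.default()
        years = list(periods.p1) + list(periods.p2)
        values = [700109.0] * 16 + [509184.0] * 18
        assert period_summary(years, values, periods).percent == -27

    def test_2012_gap_gives_n2_18(self):
        rng = np.random.default_rng(2)
        years = np.arange(1984, 2019)
        vals = rng.random(35) + 1
        vals[years == 2012] = np.nan
        s = period_summary(years, vals)
        assert s.n2 == 18

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match=">=2"):
            period_summary([1984, 2000, 2001], [1.0, 2.0, 3.0])


class TestChangeVector:
    def test_identical_periods_zero_vector(self):
        periods = PeriodDefinition(p1=(0, 1, 2, 3), p2=(4, 5, 6, 7))
        areas = [4.0, 6.0, 5.0, 7.0] * 2
        cv = change_vector(range(8), areas, periods)
        assert cv.magnitude == pytest.approx(0, abs=1e-12)

    def test_mean_shift_only(self):
        # record max (year 4, outside both periods) is 10, so P1 proportions
        # are all 0.6 and P2 all 0.4
        periods = PeriodDefinition(p1=(0, 1), p2=(2, 3))
        cv = change_vector(range(5), [6.0, 6.0, 4.0, 4.0, 10.0], periods)
        assert cv.d_mean == pytest.approx(-0.2)
        assert cv.d_var == pytest.approx(0.0)

    def test_variance_axis_only(self):
        periods = PeriodDefinition(p1=(0, 1, 2), p2=(3, 4, 5))
        # equal means (0.6 of max), P2 spread larger
        areas = [6.0, 6.0, 6.0, 4.0, 6.0, 8.0]
        cv = change_vector(range(6), areas, periods)
        assert cv.d_mean == pytest.approx(0.0, abs=1e-12)
        assert cv.d_var > 0

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        periods = PeriodDefinition.default()
        years = np.array(periods.p1 + periods.p2)
        areas = rng.random(34) * 100 + 1
        a = change_vector(years, areas, periods)
        b = change_vector(years, areas * 17.3, periods)
        assert a.d_mean == pytest.approx(b.d_mean)
        assert a.d_var == pytest.approx(b.d_var)

    def test_zero_max_error(self):
        with pytest.raises(ValueError, match="positive"):
            change_vector([1, 2, 3, 4], [0, 0, 0, 0],
                          PeriodDefinition(p1=(1, 2), p2=(3, 4)))


class TestRegionalRollup:
    def _series(self, p1_level, p2_level, periods):
        years = list(periods.p1) + list(periods.p2)
        vals = [p1_level] * len(periods.p1) + [p2_level] * len(periods.p2)
        return years, vals

    def test_single_watershed_equals_summary(self):
        periods = PeriodDefinition.default()
        years, vals = self._series(10.0, 8.0, periods)
        roll = regional_rollup({"w1": (years, vals)}, periods)
        s = period_summary(years, vals, periods)
        assert roll.p1_mean == s.p1_mean and roll.percent == s.percent

    def test_pooled_percent_from_sums(self):
        periods = PeriodDefinition.default()
        a = self._series(100.0, 80.0, periods)  # -20%
        b = self._series(100.0, 60.0, periods)  # -40%
        roll = regional_rollup({"a": a, "b": b}, periods)
        assert roll.percent == -30

    def test_significance_counts(self):
        periods = PeriodDefinition.default()
        rng = np.random.default_rng(1)
        series = {}
        for i in range(6):
            years = list(periods.p1) + list(periods.p2)
            vals = np.concatenate([
                rng.normal(100, 2, len(periods.p1)),
                rng.normal(60, 2, len(periods.p2)),  # strong decline
            ])
            series[f"w{i}"] = (years, vals)
        roll = regional_rollup(series, periods)
        assert roll.n_wilcoxon_sig == 6 and roll.n_trend_sig == 6

    def test_mixed_units_rejected(self):
        periods = PeriodDefinition.default()
        years, vals = self._series(10.0, 8.0, periods)
        with pytest.raises(ValueError, match="units"):
            regional_rollup(
                {"a": (years, vals), "b": (years, vals)},
                periods,
                units={"a": "ha", "b": "mm"},
            )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            regional_rollup({})
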