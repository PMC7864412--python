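"""The six reference-level baselines against hand-computed and oracle values."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stmfx import (EstimatorError, HemisphereSeason, ReferencePeriod,
                   compute_reference, quantile_linear, summer_average_week,
                   week_specific_average, week_specific_lower_quartile,
                   week_specific_trend, yearly_average_week,
                   yearly_lower_quartile_week)

from conftest import make_series, rect_series
from oracles import oracle_quantile


class TestQuantileLinear:
    @pytest.mark.parametrize("values, p, expected", [
        ([1, 2, 3, 4], 0.25, 1.75),                       # h = 1.75
        ([90, 92, 95, 100, 105, 110, 115, 120], 0.25, 94.25),  # h = 2.75
        ([7.0], 0.0, 7.0),
        ([7.0], 0.9, 7.0),
        ([1, 2, 3, 4], 0.0, 1.0),
        ([1, 2, 3, 4], 1.0, 4.0),
    ])
    def test_type7_closed_form_cases(self, values, p, expected):
        assert quantile_linear(values, p) == pytest.approx(expected, abs=1e-12)

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            quantile_linear([], 0.5)
        with pytest.raises(ValueError):
            quantile_linear([1.0, float("nan")], 0.5)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30),
           st.floats(0, 1))
    def test_matches_independent_closed_form(self, values, p):
        assert quantile_linear(values, p) == pytest.approx(
            oracle_quantile(values, p), rel=1e-9, abs=1e-9)


class TestWeekSpecificAverage:
    def test_hand_computed_means(self):
        series, period = rect_series({1: [100, 110], 2: [90, 95, 100, 105, 110]})
        ref = week_specific_average(series, ReferencePeriod((2015, 2016)), [1])
        assert ref.level[1] == 105.0
        ref2 = week_specific_average(series, period, [2])
        assert ref2.level[2] == 100.0

    def test_singleton_period_is_identity(self):
        series, _ = rect_series({1: [100.0], 2: [120.0]}, first_year=2019)
        ref = week_specific_average(series, ReferencePeriod((2019,)), [1, 2])
        assert ref.level == {1: 100.0, 2: 120.0}

    def test_ragged_denominator_uses_available_years(self):
        # week 2 missing in 2016: mean over the single observing year
        series = make_series({(2015, 1): 10.0, (2016, 1): 20.0, (2015, 2): 7.0})
        ref = week_specific_average(series, ReferencePeriod((2015, 2016)), [1, 2])
        assert ref.level == {1: 15.0, 2: 7.0}
        assert ref.diagnostics["n_obs"] == {1: 2, 2: 1}

    def test_week_with_no_observations_errors(self):
        series = make_series({(2015, 1): 10.0})
        with pytest.raises(EstimatorError, match="week 2"):
            week_specific_average(series, ReferencePeriod((2015,)), [1, 2])


class TestWeekSpecificTrend:
    def test_collinear_values_extrapolate_exactly(self):
        series, period = rect_series({1: [100, 102, 104]}, first_year=2017)
        ref = week_specific_trend(series, period, 2020, [1])
        assert ref.level[1] == pytest.approx(106.0, rel=1e-12)
        a, b = ref.diagnostics["coefficients"][1]
        assert b == pytest.approx(2.0, rel=1e-9)
        assert a + b * 2020 == pytest.approx(106.0, rel=1e-9)

    def test_constant_series_predicts_the_constant(self):
        series, period = rect_series({1: [50, 50, 50, 50]})
        ref = week_specific_trend(series, period, 2030, [1])
        assert ref.level[1] == 50.0

    def test_alternating_values_follow_closed_form_ols(self):
        # values 10,20,10,20 over 2016-2019: slope 2, mean 15 at 2017.5
        series, period = rect_series({1: [10, 20, 10, 20]}, first_year=2016)
        ref = week_specific_trend(series, period, 2020, [1])
        assert ref.level[1] == pytest.approx(20.0, rel=1e-12)

    def test_single_reference_year_rejected(self):
        series, _ = rect_series({1: [10.0]}, first_year=2019)
        with pytest.raises(EstimatorError, match="at least 2"):
            week_specific_trend(series, ReferencePeriod((2019,)), 2020, [1])

    def test_week_with_one_observation_rejected_naming_week(self):
        series = make_series({(2015, 1): 1.0, (2016, 1): 2.0, (2015, 2): 5.0})
        with pytest.raises(EstimatorError, match="week 2"):
            week_specific_trend(series, ReferencePeriod((2015, 2016)), 2020, [1, 2])


class TestWeekSpecificLowerQuartile:
    @pytest.mark.parametrize("values, expected", [
        ([90, 92, 95, 100, 105, 110, 115, 120], 91.0),  # Q1=94.25 -> {90,92}
        ([100, 100, 100, 100], 100.0),                  # all tied at Q1
        ([1, 2, 3, 4], 1.0),                            # Q1=1.75 -> {1}
    ])
    def test_hand_computed_low_means(self, values, expected):
        series, period = rect_series({1: values}, first_year=2010)
        ref = week_specific_lower_quartile(series, period, [1])
        assert ref.level[1] == pytest.approx(expected, abs=1e-12)

    def test_boundary_ties_included(self):
        # Q1 of {10,10,10,1000} is 10: all three tied values enter the mean
        series, period = rect_series({1: [10, 10, 10, 1000]}, first_year=2010)
        ref = week_specific_lower_quartile(series, period, [1])
        assert ref.level[1] == 10.0


class TestConstantMethods:
    def test_yearly_average_week_of_indexed_means(self):
        # x̄_i = i for weeks 1..4 (single reference year) -> constant 2.5
        series, period = rect_series({i: [float(i)] for i in range(1, 5)},
                                     first_year=2019)
        ref = yearly_average_week(series, period, range(1, 5))
        assert ref.is_constant
        assert ref.level[3] == 2.5
        ref10 = yearly_average_week(
            make_series({(2019, i): float(i) for i in range(1, 11)}),
            period, range(1, 11))
        assert ref10.level[1] == 5.5

    def test_summer_average_excludes_winter_weeks(self):
        north = HemisphereSeason.north()
        # 1 on winter weeks, 0 elsewhere -> summer average 0
        vals = {(2019, i): (1.0 if i in north.winter_weeks else 0.0)
                for i in range(1, 53)}
        ref = summer_average_week(make_series(vals), ReferencePeriod((2019,)),
                                  range(1, 53), north)
        assert ref.level[1] == 0.0
        # x̄_i = i -> mean of 13..47 = 30
        ref2 = summer_average_week(
            make_series({(2019, i): float(i) for i in range(1, 53)}),
            ReferencePeriod((2019,)), range(1, 53), north)
        assert ref2.level[1] == pytest.approx(30.0)
        assert set(ref2.weeks) == set(range(1, 53))

    def test_summer_average_errors_when_only_winter_available(self):
        vals = {(2019, i): 1.0 for i in range(1, 13)}
        with pytest.raises(EstimatorError, match="non-winter"):
            summer_average_week(make_series(vals), ReferencePeriod((2019,)),
                                range(1, 13), HemisphereSeason.north())

    @pytest.mark.parametrize("pool, expected", [
        (list(range(1, 9)), 1.5),          # Q1=2.75 -> mean{1,2}
        ([10, 10, 10, 1000], 10.0),        # Q1=10 -> mean of the three 10s
    ])
    def test_yearly_lower_quartile_pools_all_weeks(self, pool, expected):
        vals = {(2019, i + 1): float(v) for i, v in enumerate(pool)}
        ref = yearly_lower_quartile_week(make_series(vals),
                                         ReferencePeriod((2019,)))
        assert ref.is_constant
        assert ref.level[1] == pytest.approx(expected, abs=1e-12)


class TestSeasonDefinitions:
    def test_hemisphere_partitions(self):
        north = HemisphereSeason.north()
        south = HemisphereSeason.south()
        assert north.winter_weeks == set(range(1, 13)) | set(range(48, 53))
        assert north.nonwinter_weeks == set(range(13, 48))
        assert south.winter_weeks == set(range(22, 39))
        assert south.nonwinter_weeks == set(range(1, 22)) | set(range(39, 53))
        for h in (north, south):
            assert h.winter_weeks | h.nonwinter_weeks == set(range(1, 53))
            assert not h.winter_weeks & h.nonwinter_weeks

    def test_country_lookup_defaults_north(self):
        assert HemisphereSeason.for_country("DEUTNP").hemisphere == "north"
        assert HemisphereSeason.for_country("CHL").hemisphere == "south"


class TestDispatchAndPeriods:
    def test_default_period_caps_at_seven_preceding_years(self):
        vals = {(y, 1): 1.0 for y in range(2005, 2021)}
        series = make_series(vals)
        period = ReferencePeriod.preceding(series, 2020)
        assert period.years == tuple(range(2013, 2020))

    def test_period_years_must_exist_in_series(self):
        series = make_series({(2019, 1): 1.0})
        with pytest.raises(EstimatorError, match="2010"):
            week_specific_average(series, ReferencePeriod((2010, 2019)), [1])

    def test_dispatch_matches_direct_calls(self):
        series, period = rect_series(
            {i: [100.0 + i, 110.0 + i, 90.0 + i] for i in range(1, 53)})
        direct = week_specific_average(series, period, range(1, 53))
        via = compute_reference(series, "wsa", period, weeks=range(1, 53))
        assert via.level == direct.level

    def test_unknown_method_rejected(self):
        series, period = rect_series({1: [1.0, 2.0]})
        with pytest.raises(EstimatorError, match="unknown method"):
            compute_reference(series, "serfling", period, weeks=[1])


class TestWeek53Fallback:
    def test_week53_carried_forward_when_absent_from_reference(self):
        vals = {(y, w): float(w) for y in (2018, 2019) for w in range(1, 53)}
        vals[(2020, 53)] = 99.0
        vals.update({(2020, w): float(w) for w in range(1, 53)})
        series = make_series(vals)
        ref = week_specific_average(series, ReferencePeriod((2018, 2019)),
                                    range(1, 54))
        assert ref.level[53] == ref.level[52]
        assert ref.diagnostics["week53_fallback"]

    def test_week53_computed_when_reference_contains_it(self):
        vals = {(2015, 53): 40.0, (2020, 53): 50.0}
        vals.update({(y, w): 1.0 for y in (2015, 2020) for w in range(1, 53)})
        series = make_series(vals)
        ref = week_specific_average(series, ReferencePeriod((2015,)), [52, 53])
        assert ref.level[53] == 40.0
        assert not ref.diagnostics["week53_fallback"]


class TestOrderInvariants:
    def test_lower_quartile_below_average_per_week(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            series, period = rect_series(
                {i: rng.gamma(10, 100, size=6).tolist() for i in range(1, 20)})
            avg = week_specific_average(series, period, range(1, 20))
            low = week_specific_lower_quartile(series, period, range(1, 20))
            for w in range(1, 20):
                assert low.level[w] <= avg.level[w] + 1e-9

    def test_permutation_invariance_of_record_order(self):
        rng = np.random.default_rng(4)
        data = {(2015 + k, w): float(rng.gamma(10, 100))
                for k in range(5) for w in range(1, 53)}
        period = ReferencePeriod(tuple(range(2015, 2020)))
        shuffled = dict(reversed(list(data.items())))
        for method in ("wsa", "wst", "wsq", "yaw", "saw", "ylq"):
            a = compute_reference(make_series(data), method, period,
                                  weeks=range(1, 53), target_year=2020)
            b = compute_reference(make_series(shuffled), method, period,
                                  weeks=range(1, 53), target_year=2020)
            assert a.level == b.level
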