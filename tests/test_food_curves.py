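"""Curve construction: interpolation, requirement stacking, scaling, smoothing."""

import numpy as np
import pandas as pd
import pytest

import phenosync as ps
from phenosync.food_curves import CurveError, _penalty_matrix

from conftest import gaussian_series


class TestInterpolateBiomass:
    def test_reproduces_samples_exactly(self):
        s = gaussian_series()
        curve = ps.interpolate_biomass(s, (100, 180))
        on_samples = curve.value_on(s.days)
        np.testing.assert_allclose(on_samples, s.biomass, rtol=1e-9)

    def test_linear_data_interpolated_linearly(self):
        days = np.array([120, 125, 130, 135, 140])
        vals = 10.0 - 0.5 * (days - 120)  # straight declining line
        s = ps.FrassSeries(1, days, vals)
        curve = ps.interpolate_biomass(s, (120, 140))
        expect = 10.0 - 0.5 * (curve.days - 120)
        np.testing.assert_allclose(curve.values, expect, atol=1e-9)

    def test_positive_boundary_slope_zeroes_tail(self):
        # rising at the right edge: everything beyond the last sample is zero
        days = np.array([120, 124, 128, 132])
        vals = np.array([1.0, 0.5, 0.6, 2.0])
        curve = ps.interpolate_biomass(ps.FrassSeries(1, days, vals), (110, 150))
        assert np.all(curve.values[curve.days > 132] == 0.0)

    def test_declining_boundary_extends_linearly_then_clips(self):
        s = gaussian_series(peak=140, window=(125, 155))
        curve = ps.interpolate_biomass(s, (100, 180))
        left = curve.values[curve.days < 125]
        # linear decline towards zero going left, no negatives anywhere
        assert np.all(np.diff(left) >= 0)
        assert np.all(curve.values >= 0)
        assert curve.values[0] == 0.0  # far tail clipped at zero

    def test_too_few_samples_rejected(self):
        s = ps.FrassSeries(1, np.array([120, 125]), np.array([1.0, 2.0]))
        with pytest.raises(CurveError):
            ps.interpolate_biomass(s, (100, 180))

    def test_peak_recovery_noiseless_bump(self):
        # dense 3-day sampling of a noiseless bump localises the peak to ±1 day
        for peak in (133, 140, 147):
            s = gaussian_series(peak=peak)
            curve = ps.interpolate_biomass(s, (100, 180))
            assert abs(ps.curve_stats(curve).peak_date - peak) <= 1


class TestCurveStats:
    def test_symmetric_triangle(self):
        days = np.arange(100, 121)
        vals = 10.0 - np.abs(days - 110)
        st = ps.curve_stats(ps.DailyCurve(1, days, vals, kind="availability"))
        assert st.peak_date == 110
        assert st.peak_height == 10.0
        assert abs(st.skewness) < 1e-12

    def test_tie_breaks_to_earliest_day(self):
        days = np.arange(100, 120)
        vals = np.ones_like(days, dtype=float)
        vals[5] = vals[12] = 7.0  # equal maxima at days 105 and 112
        st = ps.curve_stats(ps.DailyCurve(1, days, vals, kind="availability"))
        assert st.peak_date == 105

    def test_point_mass_rejected(self):
        days = np.arange(100, 110)
        vals = np.zeros_like(days, dtype=float)
        vals[3] = 5.0
        with pytest.raises(CurveError):
            ps.curve_stats(ps.DailyCurve(1, days, vals, kind="availability"))

    def test_all_zero_rejected(self):
        c = ps.DailyCurve(1, np.arange(5), np.zeros(5), kind="availability")
        with pytest.raises(CurveError):
            ps.curve_stats(c)


class TestEnergyConversions:
    @pytest.mark.parametrize("kj,grams", [(21.4, 5.0), (0.0, 0.0), (10.7, 2.5)])
    def test_grams_required(self, kj, grams):
        assert ps.grams_required(kj) == pytest.approx(grams)

    def test_negative_energy_rejected(self):
        with pytest.raises(CurveError):
            ps.grams_required(-1.0)

    @pytest.mark.parametrize("age,grams", [(5, 2.57), (10, 3.97), (15, 4.51)])
    def test_requirement_series(self, age, grams):
        assert ps.requirement_per_nestling(age) == grams

    @pytest.mark.parametrize("age", [4, 16, 0])
    def test_requirement_outside_window_rejected(self, age):
        with pytest.raises(CurveError):
            ps.requirement_per_nestling(age)


class TestRequirementCurve:
    def test_single_nestling_total_is_series_sum(self, toy_breeding):
        one = toy_breeding[toy_breeding["brood_id"] == "b2"]  # 1 nestling
        curve = ps.build_requirement_curve(one, 2000, (120, 170))
        assert curve.values.sum() == pytest.approx(sum(ps.REQUIREMENT_G))  # 42.41 g

    def test_day_value_arithmetic(self, toy_breeding):
        # 8 nestlings, hatch day 130: age 10 falls on day 140 -> 8 x 3.97 g
        one = toy_breeding[toy_breeding["brood_id"] == "b1"]
        curve = ps.build_requirement_curve(one, 2000, (120, 170))
        assert curve.value_on(140)[()] == pytest.approx(8 * 3.97)

    def test_additivity_and_failed_brood_excluded(self, toy_breeding):
        both = ps.build_requirement_curve(toy_breeding, 2000, (120, 170))
        doubled = pd.concat([toy_breeding, toy_breeding.assign(
            brood_id=toy_breeding["brood_id"] + "x")], ignore_index=True)
        twice = ps.build_requirement_curve(doubled, 2000, (120, 170))
        np.testing.assert_allclose(twice.values, 2 * both.values)
        # failed brood b3 contributes nothing: totals match b1 (8 chicks) + b2 (1)
        assert both.values.sum() == pytest.approx(9 * 42.41)

    def test_brute_force_oracle(self, small_study):
        # independent brute-force day-by-day sum over broods
        truth, study = small_study
        year = int(study.breeding["year"].iloc[0])
        curve = ps.build_requirement_curve(study.breeding, year, truth.season_window)
        sub = study.breeding[(study.breeding["year"] == year) & (~study.breeding["failed"])]
        for day in range(truth.season_window[0], truth.season_window[1] + 1, 7):
            expect = 0.0
            for _, b in sub.iterrows():
                age = day - b["hatch_date"]
                if 5 <= age <= 15:
                    expect += float(b["brood_size_d15"]) * ps.REQUIREMENT_G[age - 5]
            assert curve.value_on(day)[()] == pytest.approx(expect)


class TestScaling:
    def test_single_year_max_becomes_one(self):
        c = ps.DailyCurve(1, np.arange(3), np.array([1.0, 7.0, 2.0]), kind="availability")
        (s,) = ps.scale_across_seasons([c])
        assert s.values.max() == 1.0 and s.scaled

    def test_height_ratios_preserved(self):
        c1 = ps.DailyCurve(1, np.arange(3), np.array([0.0, 7.0, 1.0]), kind="availability")
        c2 = ps.DailyCurve(2, np.arange(3), np.array([0.0, 3.5, 1.0]), kind="availability")
        s1, s2 = ps.scale_across_seasons([c1, c2])
        assert s1.values.max() == pytest.approx(1.0)
        assert s2.values.max() == pytest.approx(0.5)

    def test_idempotent(self):
        c = ps.DailyCurve(1, np.arange(3), np.array([1.0, 7.0, 2.0]), kind="availability")
        once = ps.scale_across_seasons([c])
        twice = ps.scale_across_seasons(once)
        np.testing.assert_array_equal(once[0].values, twice[0].values)

    def test_mixed_kinds_rejected(self):
        a = ps.DailyCurve(1, np.arange(3), np.ones(3), kind="availability")
        r = ps.DailyCurve(1, np.arange(3), np.ones(3), kind="requirement")
        with pytest.raises(CurveError):
            ps.scale_across_seasons([a, r])

    def test_scaled_sets_attain_max_one_per_kind(self, small_curves):
        for group in (small_curves.avail_scaled, small_curves.req_scaled):
            gmax = max(c.values.max() for c in group.values())
            assert gmax == pytest.approx(1.0)


class TestSmoothingSpline:
    def test_full_df_interpolates(self):
        rng = np.random.default_rng(0)
        x = np.arange(20.0)
        y = rng.standard_normal(20)
        np.testing.assert_allclose(ps.smoothing_spline(x, y, 20), y)

    def test_df_two_is_least_squares_line(self):
        x = np.arange(30.0)
        y = 2.0 + 0.3 * x + np.sin(x)
        f = ps.smoothing_spline(x, y, 2.0 + 1e-6)
        coef = np.polyfit(x, y, 1)
        np.testing.assert_allclose(f, np.polyval(coef, x), atol=1e-3)

    def test_hat_trace_matches_requested_df(self):
        x = np.arange(30.0)
        K = _penalty_matrix(x)
        # recover lambda implicitly: smoother applied to identity columns
        S = np.column_stack([
            ps.smoothing_spline(x, e, 10.0) for e in np.eye(30)
        ])
        assert np.trace(S) == pytest.approx(10.0, abs=1e-4)
        # symmetric hat matrix, as (I + lambda K)^-1 must be
        np.testing.assert_allclose(S, S.T, atol=1e-10)

    def test_linear_functions_unshrunk(self):
        # the penalty null space (straight lines) passes through untouched
        x = np.arange(25.0)
        y = 1.5 - 0.2 * x
        np.testing.assert_allclose(ps.smoothing_spline(x, y, 6.0), y, atol=1e-8)
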