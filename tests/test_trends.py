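"""Per-pixel trends, normalized index, change vectors, zones, and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import waterbal as wb
from waterbal.simulator import AnnualSeries

from ._reference import ols_ref

YEARS = np.arange(1980, 2020)


class TestPixelTrend:
    def test_exact_linear_series_recovered(self):
        res = wb.pixel_trend(YEARS, 2.0 * YEARS + 7.0)
        assert res.slope == pytest.approx(2.0, abs=1e-10)
        assert res.intercept == pytest.approx(7.0, abs=1e-6)

    def test_constant_series_has_zero_slope(self):
        res = wb.pixel_trend(YEARS, np.full(40, 123.0))
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(21)
        y = 1.5 * YEARS[:10] + rng.normal(0, 20, 10)
        res = wb.pixel_trend(YEARS[:10], y)
        slope_ref, intercept_ref = ols_ref(list(YEARS[:10].astype(float)), list(y))
        assert res.slope == pytest.approx(slope_ref, abs=1e-10)
        assert res.intercept == pytest.approx(intercept_ref, abs=1e-6)

    def test_too_few_points_gives_sentinel_with_reason(self):
        res = wb.pixel_trend([1980, 1981], [1.0, 2.0])
        assert np.isnan(res.slope) and res.reason is not None

    def test_missing_years_dropped_pairwise(self):
        y = 2.0 * YEARS + 7.0
        y[5] = np.nan
        res = wb.pixel_trend(YEARS, y)
        assert res.slope == pytest.approx(2.0, abs=1e-10)
        assert res.n == 39

    def test_slope_invariant_to_year_shift(self):
        rng = np.random.default_rng(2)
        y = rng.normal(100, 10, 40)
        a = wb.pixel_trend(YEARS, y)
        b = wb.pixel_trend(YEARS - 1980, y)
        assert a.slope == pytest.approx(b.slope, abs=1e-9)

    def test_grid_agrees_with_scalar_path(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(300, 30, (40, 3, 4))
        vals[4, 1, 2] = np.nan
        g = wb.trend_grid(YEARS, vals)
        for r in range(3):
            for c in range(4):
                s = wb.pixel_trend(YEARS, vals[:, r, c])
                assert g["slope"][r, c] == pytest.approx(s.slope, abs=1e-10)
                assert g["normalized_index"][r, c] == pytest.approx(
                    s.normalized_index, abs=1e-10)


class TestNormalizedIndex:
    @pytest.mark.parametrize("slope,mean,expected", [
        (5.0, 250.0, 0.2),
        (-3.0, 300.0, -0.1),
        (0.0, 42.0, 0.0),
    ])
    def test_arithmetic(self, slope, mean, expected):
        assert wb.normalized_index(slope, mean) == pytest.approx(expected, abs=1e-12)

    def test_zero_mean_is_undefined(self):
        assert np.isnan(wb.normalized_index(5.0, 0.0))

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.01, 1000.0))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(6)
        y = rng.gamma(5.0, 50.0, 40) + 10
        a = wb.pixel_trend(YEARS, y)
        b = wb.pixel_trend(YEARS, c * y)
        assert b.normalized_index == pytest.approx(a.normalized_index,
                                                   rel=1e-9, abs=1e-12)


class TestPeriodMeans:
    def test_identical_periods_identical_means(self):
        vals = np.arange(40.0)
        m1, m2 = wb.period_means(YEARS, vals, (1980, 1999), (1980, 1999))
        assert m1 == m2

    def test_linear_series_means_are_period_midpoint_values(self):
        vals = YEARS.astype(float)  # value == year
        m1, m2 = wb.period_means(YEARS, vals, (1980, 1999), (2000, 2019))
        assert m1 == pytest.approx(1989.5) and m2 == pytest.approx(2009.5)

    def test_step_change_recovered(self):
        vals = np.where(YEARS >= 2000, 110.0, 100.0)
        m1, m2 = wb.period_means(YEARS, vals, (1980, 1999), (2000, 2019))
        assert m2 - m1 == pytest.approx(10.0)

    def test_empty_period_errors(self):
        with pytest.raises(ValueError, match="1960"):
            wb.period_means(YEARS, YEARS.astype(float), (1950, 1960), (2000, 2019))


class TestChangeVector:
    def test_three_four_five_triangle(self):
        cv = wb.change_vector(300.0, 400.0, 303.0, 404.0)
        assert cv.intensity == 5.0
        assert cv.direction_class == "+CWD+AET"

    def test_no_change(self):
        cv = wb.change_vector(300.0, 400.0, 300.0, 400.0)
        assert cv.intensity == 0.0 and cv.direction_class == "no change"

    def test_western_drying_signature(self):
        cv = wb.change_vector(500.0, 300.0, 520.0, 280.0)
        assert cv.direction_class == "+CWD-AET"

    def test_swapping_periods_preserves_intensity_and_negates_displacement(self):
        a = wb.change_vector(310.0, 200.0, 350.0, 170.0)
        b = wb.change_vector(350.0, 170.0, 310.0, 200.0)
        assert a.intensity == b.intensity
        assert a.displacement == (-b.displacement[0], -b.displacement[1])

    def test_direction_codes_match_sign_oracle(self):
        # brute-force oracle over all 9 sign combinations of the displacement
        def oracle(dc, da):
            if dc == 0 and da == 0:
                return "no change"
            c = "+" if dc >= 0 else "-"
            a = "+" if da >= 0 else "-"
            return f"{c}CWD{a}AET"

        for dc in (-7.0, 0.0, 7.0):
            for da in (-3.0, 0.0, 3.0):
                cv = wb.change_vector(100.0, 200.0, 100.0 + dc, 200.0 + da)
                assert cv.direction_class == oracle(dc, da), (dc, da)


class TestBivariateZones:
    def test_equal_counts_on_independent_uniforms(self):
        rng = np.random.default_rng(13)
        aet = rng.random((100, 100))
        cwd = rng.random((100, 100))
        labels = wb.bivariate_zones(aet, cwd, 9)
        counts = np.bincount(labels.ravel(), minlength=9)
        assert len(counts) == 9
        np.testing.assert_allclose(counts / labels.size, 1 / 9, atol=0.02)

    def test_single_zone_contains_everything(self):
        rng = np.random.default_rng(1)
        labels = wb.bivariate_zones(rng.random((5, 5)), rng.random((5, 5)), 1)
        assert np.all(labels == 0)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        aet = rng.random((40, 40)) * 500
        cwd = rng.random((40, 40)) * 800
        base = wb.bivariate_zones(aet, cwd, 9)
        warped = wb.bivariate_zones(np.exp(aet / 200.0), cwd, 9)
        np.testing.assert_array_equal(base, warped)

    def test_nodata_labelled_minus_one_and_nonsquare_rejected(self):
        aet = np.array([[1.0, np.nan], [2.0, 3.0]])
        cwd = np.ones((2, 2))
        labels = wb.bivariate_zones(aet, cwd, 4)
        assert labels[0, 1] == -1
        with pytest.raises(ValueError, match="square"):
            wb.bivariate_zones(aet, cwd, 5)


class TestCategorySummary:
    def test_single_category_equals_whole_grid(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(10, 2, (6, 6))
        table = wb.category_summary({"aet": vals}, np.zeros((6, 6), dtype=int))
        assert len(table) == 1
        assert table["mean"].iloc[0] == pytest.approx(vals.mean())
        assert table["count"].iloc[0] == 36

    def test_disjoint_constants_recovered_and_counts_sum(self):
        mask = np.repeat([0, 1], 18).reshape(6, 6)
        vals = np.where(mask == 0, 5.0, 9.0)
        table = wb.category_summary({"cwd": vals}, mask).set_index("category")
        assert table.loc[0, "mean"] == 5.0 and table.loc[1, "mean"] == 9.0
        assert int(table["count"].sum()) == 36

    def test_misaligned_mask_rejected(self):
        with pytest.raises(wb.GridAlignmentError):
            wb.category_summary({"aet": np.ones((3, 3))}, np.zeros((2, 2)))


class TestCentroidVectors:
    def _annual(self):
        rng = np.random.default_rng(9)
        aet = rng.normal(300, 5, (40, 4, 4))
        cwd = rng.normal(400, 5, (40, 4, 4))
        return AnnualSeries(YEARS, {"aet": aet, "cwd": cwd})

    def test_point_at_cell_center_matches_that_cell(self):
        annual = self._annual()
        transform = wb.Affine.from_origin(0.0, 4.0, 1.0, 1.0)
        table, skipped = wb.centroid_vectors(
            annual, [("p", 1.5, 2.5)], transform, (1980, 1999), (2000, 2019))
        assert skipped == 0
        cwd1, cwd2 = wb.period_means(YEARS, annual.data["cwd"],
                                     (1980, 1999), (2000, 2019))
        aet1, aet2 = wb.period_means(YEARS, annual.data["aet"],
                                     (1980, 1999), (2000, 2019))
        cv = wb.change_vector(cwd1[1, 1], aet1[1, 1], cwd2[1, 1], aet2[1, 1])
        assert table["intensity"].iloc[0] == pytest.approx(cv.intensity)
        assert (table["row"].iloc[0], table["col"].iloc[0]) == (1, 1)

    def test_out_of_bounds_point_skipped_with_count(self):
        annual = self._annual()
        transform = wb.Affine.from_origin(0.0, 4.0, 1.0, 1.0)
        with pytest.warns(UserWarning, match="outside"):
            table, skipped = wb.centroid_vectors(
                annual, [("in", 0.5, 0.5), ("out", 99.0, 99.0)], transform,
                (1980, 1999), (2000, 2019))
        assert skipped == 1 and len(table) == 1

    def test_coincident_points_get_identical_vectors(self):
        annual = self._annual()
        transform = wb.Affine.from_origin(0.0, 4.0, 1.0, 1.0)
        table, _ = wb.centroid_vectors(
            annual, [("a", 2.2, 1.2), ("b", 2.2, 1.2)], transform,
            (1980, 1999), (2000, 2019))
        assert table["intensity"].iloc[0] == table["intensity"].iloc[1]
        assert table["direction"].iloc[0] == table["direction"].iloc[1]
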