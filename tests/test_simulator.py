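"""Grid orchestration: consistency, determinism, aggregation, snow phenology."""

import numpy as np
import pytest

import waterbal as wb
from waterbal._calendar import NOLEAP, DailyIndex
from waterbal.soil import WaterState

from .conftest import make_site_forcing, series_to_stacks


class TestRunConsistency:
    def test_single_cell_grid_matches_step_cell_trajectory(self):
        series = make_site_forcing(365, tmean=5.0, seed=4)
        cell = wb.CellAttributes(latitude=42.0, slope=10.0, aspect=200.0,
                                 whc=120.0, snow_t50=1.0,
                                 ndvi_climatology=np.linspace(0.2, 0.8, 365))
        res = wb.run(series_to_stacks(series), cell)
        state = WaterState(0.0, 120.0)
        clim_idx = series.index.climatology_index
        for t in range(365):
            tmean = (series.tmin[t] + series.tmax[t]) / 2.0
            state, fx = wb.step_cell(state, tmean, series.precip[t], cell,
                                     int(clim_idx[t]) + 1)
            for name in ("pet", "aet", "cwd", "swe", "soil_water", "runoff"):
                assert res.outputs[name].data[t, 0, 0] == getattr(fx, name), name

    def test_chunked_equals_unchunked_bitwise(self):
        bundle = wb.make_scenario("drying_west", seed=3, shape=(6, 7), years=2)
        full = wb.run(bundle.forcing, bundle.attributes)
        tiled = wb.run(bundle.forcing, bundle.attributes, chunks=(4, 3))
        for name, stack in full.outputs.items():
            np.testing.assert_array_equal(stack.data, tiled.outputs[name].data,
                                          err_msg=name)

    def test_misaligned_grids_error_reports_shapes(self):
        bundle = wb.make_scenario("drying_west", seed=0, shape=(3, 3), years=1)
        bad = dict(bundle.forcing)
        small = bad["prcp"].data[:, :2, :2]
        bad["prcp"] = wb.GridStack("prcp", small, bad["prcp"].index, units="mm")
        with pytest.raises(wb.GridAlignmentError, match="3, 3"):
            wb.run(bad, bundle.attributes)

    def test_nodata_forcing_day_yields_nodata_outputs(self):
        series = make_site_forcing(30, precip=1.0)
        stacks = series_to_stacks(series)
        stacks["prcp"].data[10, 0, 0] = np.nan
        res = wb.run(stacks, wb.CellAttributes(latitude=40.0, whc=100.0))
        for name in ("aet", "pet", "cwd", "soil_water", "swe", "runoff"):
            assert np.isnan(res.outputs[name].data[10, 0, 0]), name
        # the run recovers after the gap: storages carried across it
        assert np.isfinite(res.outputs["aet"].data[11, 0, 0])
        assert res.outputs["soil_water"].data[11, 0, 0] <= \
            res.outputs["soil_water"].data[9, 0, 0] + series.precip[11]

    def test_mass_closure_on_small_run(self):
        bundle = wb.make_scenario("alpine_gradient", seed=2, shape=(4, 4), years=3)
        res = wb.run(bundle.forcing, bundle.attributes)
        assert np.abs(res.mass_balance["residual_per_year"]).max() < 1e-6


class TestSpinUp:
    def _desert(self):
        series = make_site_forcing(365, tmean=18.0, precip=0.0)
        return series_to_stacks(series), wb.CellAttributes(latitude=35.0, whc=60.0)

    def test_desert_cell_drains_in_one_cycle(self):
        stacks, cell = self._desert()
        state, _ = wb.spin_up(stacks, cell, n_cycles=1)
        assert float(state.swe[0, 0]) == 0.0
        assert float(state.soil[0, 0]) < 1e-6

    def test_one_cycle_equals_plain_run_end_state(self):
        stacks, cell = self._desert()
        state, conv = wb.spin_up(stacks, cell, n_cycles=1)
        res = wb.run(stacks, cell)
        assert float(state.soil[0, 0]) == float(res.final_state.soil[0, 0])
        assert conv == 0.0

    def test_cycles_converge(self):
        series = make_site_forcing(365, tmean=8.0, seed=9)
        stacks = series_to_stacks(series)
        cell = wb.CellAttributes(latitude=45.0, whc=150.0)
        _, conv = wb.spin_up(stacks, cell, n_cycles=6)
        assert conv < 0.01

    def test_rejects_zero_cycles(self):
        stacks, cell = self._desert()
        with pytest.raises(ValueError):
            wb.spin_up(stacks, cell, n_cycles=0)


class TestAnnualTotals:
    def _stack(self, data, start=(2000, 1, 1)):
        n = data.shape[0]
        return wb.GridStack("aet", data, DailyIndex.date_range(start, n, NOLEAP),
                            units="mm")

    def test_constant_one_mm_per_day_sums_to_365(self):
        ann = wb.annual_totals(self._stack(np.ones((365, 1, 1))))
        assert ann.data["aet"][0, 0, 0] == 365.0

    def test_two_year_stack_gives_two_totals(self):
        ann = wb.annual_totals(self._stack(np.ones((730, 1, 1))))
        np.testing.assert_array_equal(ann.years, [2000, 2001])

    def test_partial_year_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="2001"):
            ann = wb.annual_totals(self._stack(np.ones((400, 1, 1))))
        np.testing.assert_array_equal(ann.years, [2000])

    def test_november_flux_lands_in_later_water_year(self):
        data = np.zeros((730, 1, 1))
        idx = DailyIndex.date_range((2000, 1, 1), 730, NOLEAP)
        nov = (idx.years == 2000) & (idx.months == 11)
        data[nov] = 2.0
        with pytest.warns(UserWarning):  # partial water years at the ends
            ann = wb.annual_totals(self._stack(data), water_year=True)
        assert 2001 in ann.years
        assert ann.data["aet"][list(ann.years).index(2001), 0, 0] == 60.0

    def test_aggregation_linearity(self):
        rng = np.random.default_rng(5)
        a = rng.gamma(1.0, 2.0, (730, 2, 2))
        b = rng.gamma(1.0, 2.0, (730, 2, 2))
        s1 = wb.annual_totals(self._stack(a)).data["aet"]
        s2 = wb.annual_totals(self._stack(b)).data["aet"]
        s12 = wb.annual_totals(self._stack(a + b)).data["aet"]
        np.testing.assert_allclose(s12, s1 + s2, atol=1e-8)

    def test_empty_selection_errors(self):
        ann = wb.annual_totals(self._stack(np.ones((365, 1, 1))))
        with pytest.raises(ValueError):
            ann.mean(2010, 2020)


class TestSnowPhenology:
    def _swe_stack(self, fill):
        """One complete water year (Oct 1 2000 .. Sep 30 2001), SWE from fill(dowy)."""
        idx = DailyIndex.date_range((2000, 10, 1), 365, NOLEAP)
        dowy = np.arange(1, 366)
        data = fill(dowy).reshape(365, 1, 1).astype(float)
        return wb.GridStack("swe", data, idx, units="mm")

    def test_single_spell_metrics(self):
        stack = self._swe_stack(lambda d: np.where((d >= 50) & (d <= 100),
                                                   d.astype(float), 0.0))
        m = wb.snow_phenology(stack)
        assert m.water_years.tolist() == [2001]
        assert m.first_snow_day[0, 0, 0] == 50
        assert m.last_snow_day_plus1[0, 0, 0] == 101
        assert m.snow_days[0, 0, 0] == 51
        assert m.peak_swe[0, 0, 0] == 100.0

    def test_snow_free_year_uses_sentinels(self):
        m = wb.snow_phenology(self._swe_stack(lambda d: np.zeros_like(d, float)))
        assert m.snow_days[0, 0, 0] == 0
        assert m.first_snow_day[0, 0, 0] == -1
        assert m.last_snow_day_plus1[0, 0, 0] == -1
        assert m.peak_swe[0, 0, 0] == 0.0

    def test_disjoint_spells_counted_once_each(self):
        def fill(d):
            return np.where((d >= 10) & (d <= 20), 5.0,
                            np.where((d >= 40) & (d <= 45), 3.0, 0.0))
        m = wb.snow_phenology(self._swe_stack(fill))
        assert m.first_snow_day[0, 0, 0] == 10
        assert m.last_snow_day_plus1[0, 0, 0] == 46
        assert m.snow_days[0, 0, 0] == 17
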