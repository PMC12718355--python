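"""Slab-ocean physics, budget bookkeeping, and scenario generation."""

import numpy as np
import pytest

from stormflux import scenario as sc
from stormflux import diagnostics as dg
from stormflux.budget import budget_residual
from stormflux.grid import FieldSeries, RegularGrid
from stormflux.slab import (ScenarioTruth, SlabOceanParams, emit_budget_terms,
                            run_slab_ocean)

T0 = np.datetime64("2020-09-01T00:00:00")


def _t(hours):
    return T0 + np.timedelta64(int(hours * 3600), "s")


def _forcing(grid, n_hours, wind=0.0, mslp=1013.0):
    times = np.array([_t(h) for h in range(n_hours)])
    shape = (n_hours,) + grid.shape
    return FieldSeries.from_arrays(
        times, grid,
        {"mslp": (np.full(shape, mslp), {"units": "hPa"}),
         "wind": (np.full(shape, wind), {"units": "m s-1"})})


def _quiet_params(**kw):
    """No heat, no biology, no noise: the no-forcing limit."""
    base = dict(solar_background_wm2=0.0, growth_rate_day=0.0,
                mortality_day=0.0, noise_t_c=0.0, noise_dic_umolkg=0.0)
    base.update(kw)
    return SlabOceanParams(**base)


@pytest.fixture
def tiny_grid():
    return RegularGrid.from_bounds(24.0, 28.0, -64.0, -60.0, 1.0)


class TestNoForcingLimit:
    def test_all_state_constant(self, tiny_grid):
        res = run_slab_ocean(_forcing(tiny_grid, 24), _quiet_params())
        ds = res.fields.ds
        for var in ("sst", "sss", "dic", "alk", "nutrient", "phyto", "mld"):
            v = ds[var].values
            assert np.allclose(v, v[0], rtol=0, atol=1e-6), var

    def test_budget_terms_zero(self, tiny_grid):
        res = run_slab_ocean(_forcing(tiny_grid, 24), _quiet_params(),
                             bookkeeping=True)
        for tracer in ("dic", "temperature", "nutrient"):
            terms = emit_budget_terms(res, tracer)
            assert np.max(np.abs(terms.tendency)) == 0.0
            assert np.max(np.abs(terms.terms_sum())) == 0.0


class TestGasExchangeOnly:
    def test_dic_surface_term_is_minus_f_over_h(self, tiny_grid):
        """With entrainment and biology off, the DIC budget reduces to the
        surface gas-exchange term -F/h (unit-converted)."""
        params = _quiet_params(entrain_efficiency=0.0, entrain_cap_ms=0.0)
        res = run_slab_ocean(_forcing(tiny_grid, 48, wind=10.0), params,
                             bookkeeping=True)
        terms = emit_budget_terms(res, "dic")
        assert np.max(np.abs(terms.v_diff)) == 0.0
        assert np.max(np.abs(terms.bio)) == 0.0
        flux_mol = res.fields.ds["co2_flux"].values / 1e3 / 86400.0
        expected = -flux_mol * 1e6 / params.rho0 / params.h0_m
        assert terms.surface == pytest.approx(expected, rel=1e-5)
        res2, summary = budget_residual(terms)
        assert summary["normalized_residual"] < 1e-6


class TestConservation:
    def test_heat_closure(self, scenario_result):
        """Mixed-layer heat content change equals integrated surface plus
        entrainment heat fluxes within 0.1%."""
        a = scenario_result.run.audit
        dh = a["heat_content_j_m2"][-1] - a["heat_content_j_m2"][0]
        src = a["surface_heat_j_m2"] + a["entrain_heat_j_m2"]
        assert abs(dh - src) <= 1e-3 * abs(dh)

    def test_carbon_closure_biology_off(self, tiny_grid):
        """With biology off, the DIC inventory change equals entrained carbon
        minus the integrated air-sea flux within 0.1%."""
        params = _quiet_params(solar_background_wm2=60.0)
        res = run_slab_ocean(_forcing(tiny_grid, 120, wind=18.0), params)
        a = res.audit
        d_dic = a["dic_content_mol_m2"][-1] - a["dic_content_mol_m2"][0]
        rhs = -a["co2_flux_int_mol_m2"] + a["entrain_dic_mol_m2"]
        assert abs(d_dic - rhs) <= 1e-3 * abs(d_dic)


class TestFailureModes:
    def test_non_uniform_time_axis_rejected(self, tiny_grid):
        times = np.array([_t(0), _t(1), _t(3)])
        shape = (3,) + tiny_grid.shape
        forcing = FieldSeries.from_arrays(
            times, tiny_grid,
            {"mslp": (np.full(shape, 1013.0), {"units": "hPa"}),
             "wind": (np.zeros(shape), {"units": "m s-1"})})
        with pytest.raises(ValueError, match="uniform"):
            run_slab_ocean(forcing, _quiet_params())

    def test_negative_tracer_is_hard_failure(self, tiny_grid):
        params = SlabOceanParams(growth_rate_day=60.0,
                                 half_saturation_mmolm3=1e-4,
                                 nutrient0_mmolm3=0.01,
                                 phyto0_mmolm3=1.0)
        with pytest.raises(RuntimeError, match="negative"):
            run_slab_ocean(_forcing(tiny_grid, 24, wind=5.0), params)

    def test_budget_unavailable_without_bookkeeping(self, tiny_grid):
        res = run_slab_ocean(_forcing(tiny_grid, 12), _quiet_params(),
                             bookkeeping=False)
        with pytest.raises(ValueError, match="bookkeeping"):
            emit_budget_terms(res, "dic")

    def test_param_validation(self):
        with pytest.raises(ValueError):
            SlabOceanParams(h0_m=-1.0)
        with pytest.raises(ValueError):
            SlabOceanParams(asymmetry=1.5)

    def test_truth_validation(self):
        import pandas as pd
        bad = pd.DataFrame({"track_id": [0, 0],
                            "time": np.array([_t(3), _t(1)]),
                            "lat": [20.0, 21.0], "lon": [-60.0, -60.0]})
        with pytest.raises(ValueError, match="increasing"):
            ScenarioTruth(tracks=bad)


class TestStormResponse:
    def test_wake_cooling_range_at_intense_points(self, scenario_result,
                                                  hurricane_truth):
        """Category-4 passage cools the 200-km circle by 1.0-2.5 degC
        (24 h after minus 24 h before)."""
        wd = dg.wake_delta(scenario_result.fields, "sst", hurricane_truth)
        intense = hurricane_truth["vmax_ms"].values >= 58.0
        deltas = wd["delta"].values[intense]
        assert np.all(deltas <= -1.0)
        assert np.all(deltas >= -2.5)

    def test_rightward_wake_shift(self, scenario_result, hurricane_truth):
        """More cooling on the right of the track for category-3+ points."""
        cat3 = hurricane_truth[hurricane_truth["vmax_ms"] >= 50.0]
        asym = dg.wake_semicircle_delta(scenario_result.fields, "sst", cat3)
        vals = asym["right_minus_left"].dropna()
        assert len(vals) > 0
        assert np.all(vals < 0)

    def test_mld_deepening_tens_of_meters(self, scenario_result,
                                          hurricane_truth):
        mld = scenario_result.fields.ds["mld"].values
        deepening = mld.max(axis=0) - mld[0]
        assert 20.0 <= np.percentile(deepening[deepening > 5.0], 90) <= 80.0

    def test_bloom_lags_nutrient_pulse(self, scenario_result,
                                       hurricane_truth):
        """Phytoplankton peaks 0-21 days after the nutrient-entrainment
        peak under the track."""
        ds = scenario_result.fields.ds
        mid = hurricane_truth.iloc[len(hurricane_truth) // 2]
        i = int(np.argmin(np.abs(ds["lat"].values - mid["lat"])))
        j = int(np.argmin(np.abs(ds["lon"].values - mid["lon"])))
        nut = ds["nutrient"].values[:, i, j].astype(float)
        phy = ds["phyto"].values[:, i, j].astype(float)
        pulse_h = int(np.argmax(np.diff(nut)))
        bloom_h = int(np.argmax(phy))
        lag_days = (bloom_h - pulse_h) / 24.0
        assert 0.0 <= lag_days <= 21.0

    def test_npp_increases_order_of_magnitude(self, scenario_result,
                                              hurricane_truth):
        ds = scenario_result.fields.ds
        mid = hurricane_truth.iloc[len(hurricane_truth) // 2]
        i = int(np.argmin(np.abs(ds["lat"].values - mid["lat"])))
        j = int(np.argmin(np.abs(ds["lon"].values - mid["lon"])))
        npp = ds["npp"].values[:, i, j].astype(float)
        assert npp.max() / npp[:48].mean() >= 10.0

    def test_lhf_within_observed_envelope(self, scenario_result):
        lhf = scenario_result.fields.ds["lhf"].values
        assert 400.0 <= lhf.max() <= 2000.0

    def test_slower_storm_cools_no_less(self):
        """Halving the translation speed does not decrease wake cooling."""
        from stormflux.vortex import VortexSpec

        def run(speed_ms):
            grid = RegularGrid.from_bounds(20.0, 32.0, -70.0, -56.0, 1.0)
            times = np.array([_t(h) for h in range(240)])
            dlat_h = speed_ms * 3600.0 / 111195.0
            spec = VortexSpec(
                waypoints=[(_t(24), 22.0, -63.0),
                           (_t(216), 22.0 + dlat_h * 192, -63.0)],
                vmax_ramp=[(_t(24), 20.0), (_t(48), 60.0), (_t(216), 60.0)],
                r_mw_km=40.0)
            forcing = sc.build_forcing([spec], grid, times,
                                       background_wind_ms=5.0,
                                       rng=np.random.default_rng(0))
            params = SlabOceanParams(noise_t_c=0.0, noise_dic_umolkg=0.0)
            res = run_slab_ocean(forcing, params, bookkeeping=False)
            sst = res.fields.ds["sst"].values
            return float((sst[0] - sst.min(axis=0)).max())

        fast = run(6.0)
        slow = run(3.0)
        assert slow >= fast


class TestDeterminism:
    def test_identical_seed_bitwise(self, small_config):
        a = sc.generate_scenario(small_config)
        b = sc.generate_scenario(small_config)
        for var in a.fields.data_vars:
            assert np.array_equal(a.fields.ds[var].values,
                                  b.fields.ds[var].values), var
        assert a.truth.tracks.equals(b.truth.tracks)

    def test_different_seed_differs(self, small_config):
        a = sc.generate_scenario(small_config)
        small_config.seed = small_config.seed + 1
        b = sc.generate_scenario(small_config)
        assert not np.array_equal(a.fields.ds["sst"].values,
                                  b.fields.ds["sst"].values)


class TestConfigRoundTrip:
    def test_yaml_lossless(self, small_config, tmp_path):
        p = tmp_path / "cfg.yaml"
        small_config.to_yaml(p)
        back = sc.ScenarioConfig.from_yaml(p)
        assert back.to_dict() == small_config.to_dict()
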