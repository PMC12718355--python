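"""Along-track composites and column diagnostics."""

import numpy as np
import pandas as pd
import pytest

from stormflux import diagnostics as dg
from stormflux.grid import FieldSeries, RegularGrid

from _oracles import circle_mean_bruteforce

T0 = np.datetime64("2020-09-01T00:00:00")


def _t(hours):
    return T0 + np.timedelta64(int(hours * 3600), "s")


def _fields(values, grid, times, name="f", units="1"):
    return FieldSeries.from_arrays(
        times, grid, {name: (values, {"units": units})})


@pytest.fixture
def grid():
    return RegularGrid.from_bounds(20.0, 35.0, -70.0, -50.0, 0.5)


@pytest.fixture
def times():
    return np.array([_t(h) for h in range(0, 120, 1)])


def _track(lat0=27.0, lon0=-60.0, n=5, dlat=0.3, t_start=48, dt_h=3):
    return pd.DataFrame({
        "time": [_t(t_start + dt_h * i) for i in range(n)],
        "lat": lat0 + dlat * np.arange(n),
        "lon": np.full(n, lon0)})


class TestTranslationSpeed:
    def test_two_points(self):
        # ~100 km in 3 h -> 9.26 m/s
        df = pd.DataFrame({"time": [_t(0), _t(3)],
                           "lat": [20.0, 20.8993], "lon": [-60.0, -60.0]})
        v = dg.translation_speed(df)
        assert v == pytest.approx([9.26, 9.26], abs=0.02)

    def test_stationary(self):
        df = pd.DataFrame({"time": [_t(0), _t(3), _t(6)],
                           "lat": [20.0] * 3, "lon": [-60.0] * 3})
        assert np.all(dg.translation_speed(df) == 0.0)

    def test_single_point_error(self):
        df = pd.DataFrame({"time": [_t(0)], "lat": [20.0], "lon": [-60.0]})
        with pytest.raises(ValueError):
            dg.translation_speed(df)

    def test_constant_velocity_track(self):
        # due-north motion at 6 m/s: 6*3600/111195 deg per hour
        dlat_h = 6.0 * 3600.0 / 111195.0
        df = pd.DataFrame({"time": [_t(h) for h in range(24)],
                           "lat": 20.0 + dlat_h * np.arange(24),
                           "lon": np.full(24, -60.0)})
        assert dg.translation_speed(df) == pytest.approx(6.0, abs=0.1)


class TestCircleAverage:
    def test_uniform_field(self, grid, times):
        fs = _fields(np.full((len(times),) + grid.shape, 3.7), grid, times)
        assert dg.circle_average(fs, "f", (27.0, -60.0), time=times[0]) \
            == pytest.approx(3.7)

    def test_bruteforce_equivalence(self, grid, times):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((1,) + grid.shape)
        fs = _fields(vals, grid, np.array([times[0]]))
        areas = grid.cell_areas_m2()
        for _ in range(20):
            center = (rng.uniform(21, 34), rng.uniform(-69, -51))
            radius = rng.uniform(100, 400)
            got = dg.circle_average(fs, "f", center, time=times[0],
                                    radius_km=radius)
            want = circle_mean_bruteforce(vals[0], grid.lat, grid.lon,
                                          center, radius, areas)
            assert got == pytest.approx(want, rel=1e-12)

    def test_planted_disc(self, grid, times):
        center = (27.0, -60.0)
        disc = (grid.distances_km(*center) <= 200.0).astype(float)
        fs = _fields(disc[None, :, :], grid, np.array([times[0]]))
        got = dg.circle_average(fs, "f", center, time=times[0])
        assert got == pytest.approx(1.0, abs=0.05)

    def test_empty_circle_warns_nan(self, grid, times):
        fs = _fields(np.ones((1,) + grid.shape), grid, np.array([times[0]]))
        with pytest.warns(UserWarning, match="no grid cells"):
            out = dg.circle_average(fs, "f", (-60.0, 100.0), time=times[0],
                                    radius_km=50.0)
        assert np.isnan(out)


class TestWakeDelta:
    def test_constant_field_zero(self, grid, times):
        fs = _fields(np.full((len(times),) + grid.shape, 5.0), grid, times)
        wd = dg.wake_delta(fs, "f", _track())
        assert wd["delta"].values == pytest.approx(0.0, abs=1e-12)

    def test_planted_step(self, grid, times):
        track = _track()
        vals = np.zeros((len(times),) + grid.shape)
        vals[60:] = -2.0  # step after all passage times
        fs = _fields(vals, grid, times)
        wd = dg.wake_delta(fs, "f", track)
        assert wd["delta"].values == pytest.approx(-2.0)

    def test_linearity(self, grid, times):
        rng = np.random.default_rng(3)
        vals = rng.standard_normal((len(times),) + grid.shape)
        track = _track()
        base = dg.wake_delta(_fields(vals, grid, times), "f", track)["delta"]
        scaled = dg.wake_delta(_fields(3.0 * vals + 11.0, grid, times), "f",
                               track)["delta"]
        assert scaled.values == pytest.approx(3.0 * base.values, rel=1e-9)

    def test_insufficient_coverage_nan(self, grid, times):
        fs = _fields(np.ones((len(times),) + grid.shape), grid, times)
        early = _track(t_start=10)  # t-24h precedes the series
        wd = dg.wake_delta(fs, "f", early)
        assert np.isnan(wd["delta"].values).all()


class TestAlongTrackDiagram:
    def test_constant_anomaly_zero(self, grid, times):
        fs = _fields(np.full((len(times),) + grid.shape, 2.0), grid, times)
        d = dg.along_track_diagram(fs, "f", _track(), anomaly=True)
        assert np.nanmax(np.abs(d.values)) == pytest.approx(0.0, abs=1e-12)

    def test_step_anomaly(self, grid, times):
        vals = np.zeros((len(times),) + grid.shape)
        vals[60:] = 1.5
        fs = _fields(vals, grid, times)
        d = dg.along_track_diagram(fs, "f", _track(), anomaly=True)
        assert d.values[:, -1] == pytest.approx(1.5)


class TestFoldIncrease:
    def test_arithmetic(self, grid, times):
        vals = np.ones((len(times),) + grid.shape)
        vals[40:] = 30.0
        fs = _fields(vals, grid, times, units="mmolC m-2 day-1")
        fold = dg.fold_increase(fs, "f", _track(), (times[0], times[24]))
        assert fold["fold"].values == pytest.approx(30.0)

    def test_equal_means_one(self, grid, times):
        fs = _fields(np.full((len(times),) + grid.shape, 4.0), grid, times)
        fold = dg.fold_increase(fs, "f", _track(), (times[0], times[24]))
        assert fold["fold"].values == pytest.approx(1.0)

    def test_zero_baseline_flagged(self, grid, times):
        vals = np.zeros((len(times),) + grid.shape)
        vals[40:] = 1.0
        fs = _fields(vals, grid, times)
        with pytest.warns(UserWarning, match="zero baseline"):
            fold = dg.fold_increase(fs, "f", _track(), (times[0], times[24]))
        assert np.isnan(fold["fold"].values).all()

    def test_quadratic_wind_scaling(self, grid, times):
        """With flux proportional to u^2 at fixed disequilibrium, the fold
        equals (u_passage / u_baseline)^2 analytically."""
        u = np.full(len(times), 5.0)
        u[40:] = 10.0
        vals = (u ** 2)[:, None, None] * np.ones(grid.shape)
        fs = _fields(vals, grid, times)
        fold = dg.fold_increase(fs, "f", _track(), (times[0], times[24]))
        assert fold["fold"].values == pytest.approx((10.0 / 5.0) ** 2)

    def test_overlapping_baseline_rejected(self, grid, times):
        fs = _fields(np.ones((len(times),) + grid.shape), grid, times)
        with pytest.raises(ValueError, match="disjoint"):
            dg.fold_increase(fs, "f", _track(t_start=10), (times[0], times[24]))


class TestIntegrateTrackRegion:
    def _uniform_flux_fields(self, grid, times, value):
        vals = np.full((len(times),) + grid.shape, value)
        return _fields(vals, grid, times, name="co2_flux",
                       units="mmolC m-2 day-1")

    def test_hand_arithmetic(self, grid, times):
        fs = self._uniform_flux_fields(grid, times, 10.0)
        track = _track(n=2, dt_h=24)
        total, area = dg.integrate_track_region(fs, "co2_flux", track)
        # uniform flux: total = 10 mmol/m2/day * sum_t(area_t) * dt
        # recompute the expected mass from the footprint geometry
        expected = 0.0
        tf = track["time"].values.astype("datetime64[s]").astype(float)
        t_axis = fs.times
        dt_days = 1.0 / 24.0
        for k, t in enumerate(t_axis):
            ts = t.astype("datetime64[s]").astype(float)
            if ts < tf[0] or ts > tf[-1]:
                continue
            la = np.interp(ts, tf, track["lat"].values)
            lo = np.interp(ts, tf, track["lon"].values)
            mask = grid.distances_km(la, lo) <= 200.0
            expected += 10.0 * grid.cell_areas_m2()[mask].sum() * dt_days
        expected_tgc = expected * 1e-3 * 12.011 / 1e12
        assert total == pytest.approx(expected_tgc, rel=1e-12)

    def test_printed_magnitude(self):
        """10 mmol/m2/day over 1e11 m2 for 10 days ~ 0.12 TgC."""
        mass_g = 10.0 * 1e11 * 10.0 * 12.011e-3
        assert mass_g / 1e12 == pytest.approx(0.12, abs=0.002)

    def test_zero_and_sign(self, grid, times):
        track = _track(n=2, dt_h=24)
        z, _ = dg.integrate_track_region(
            self._uniform_flux_fields(grid, times, 0.0), "co2_flux", track)
        assert z == 0.0
        neg, _ = dg.integrate_track_region(
            self._uniform_flux_fields(grid, times, -5.0), "co2_flux", track)
        assert neg < 0

    def test_window_additivity(self, grid, times):
        rng = np.random.default_rng(9)
        vals = rng.standard_normal((len(times),) + grid.shape)
        fs = _fields(vals, grid, times, name="co2_flux",
                     units="mmolC m-2 day-1")
        track = _track(n=3, dt_h=24, t_start=24)
        full, _ = dg.integrate_track_region(fs, "co2_flux", track,
                                            window=(_t(24), _t(72)))
        a, _ = dg.integrate_track_region(fs, "co2_flux", track,
                                         window=(_t(24), _t(47)))
        b, _ = dg.integrate_track_region(fs, "co2_flux", track,
                                         window=(_t(48), _t(72)))
        assert full == pytest.approx(a + b, rel=1e-12)

    def test_missing_units_rejected(self, grid, times):
        vals = np.ones((len(times),) + grid.shape)
        fs = FieldSeries.from_arrays(times, grid, {"co2_flux": (vals, {})})
        with pytest.raises(ValueError, match="units"):
            dg.integrate_track_region(fs, "co2_flux", _track(n=2, dt_h=24))


class TestCumulativeFlux:
    def test_constant_ramp(self, grid, times):
        fs = _fields(np.full((len(times),) + grid.shape, 2.0), grid, times)
        diagram = dg.along_track_diagram(fs, "f", _track())
        cum = dg.cumulative_flux(diagram)
        row = cum.values[0]
        valid = np.isfinite(row)
        # slope 2 per day on an hourly axis
        assert np.diff(row[valid]) == pytest.approx(2.0 / 24.0, rel=1e-6)

    def test_zero_flux(self, grid, times):
        fs = _fields(np.zeros((len(times),) + grid.shape), grid, times)
        cum = dg.cumulative_flux(dg.along_track_diagram(fs, "f", _track()))
        assert np.nansum(np.abs(cum.values)) == 0.0


class TestMixedLayerDepth:
    def test_linear_profile_closed_form(self):
        z = np.arange(0.0, 30.0, 0.5)
        rho = 1025.0 + 0.01 * z
        assert dg.mixed_layer_depth(z, rho, 0.03) == pytest.approx(3.0)
        assert dg.mixed_layer_depth(z, rho, 0.125) == pytest.approx(12.5)

    def test_homogeneous_returns_bottom(self):
        z = np.array([0.0, 10.0, 50.0, 200.0])
        assert dg.mixed_layer_depth(z, np.full(4, 1025.0), 0.03) == 200.0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        z = np.linspace(0, 500, 60)
        for _ in range(20):
            rho = 1024.0 + np.cumsum(rng.uniform(0, 0.05, 60))
            assert dg.mixed_layer_depth(z, rho, 0.125) >= \
                dg.mixed_layer_depth(z, rho, 0.03)

    def test_unordered_depths_rejected(self):
        with pytest.raises(ValueError):
            dg.mixed_layer_depth([0.0, 5.0, 3.0], [1025.0] * 3, 0.03)


class TestBruntVaisala:
    def test_hand_value(self):
        z = np.linspace(0, 100, 11)
        rho = 1025.0 + 0.01 * z
        _, n2 = dg.brunt_vaisala(z, rho)
        assert n2 == pytest.approx(9.81 * 0.01 / 1025.0, rel=1e-9)
        assert n2[0] == pytest.approx(9.57e-5, abs=2e-7)

    def test_homogeneous_zero(self):
        z = np.linspace(0, 100, 11)
        _, n2 = dg.brunt_vaisala(z, np.full(11, 1025.0))
        assert np.all(n2 == 0.0)

    def test_inversion_negative(self):
        z = np.linspace(0, 100, 11)
        _, n2 = dg.brunt_vaisala(z, 1025.0 - 0.01 * z)
        assert np.all(n2 < 0)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            dg.brunt_vaisala([10.0], [1025.0])


class TestInertialPeriod:
    def test_pole(self):
        assert dg.inertial_period(90.0) == pytest.approx(11.97, abs=0.01)

    def test_30_degrees(self):
        assert dg.inertial_period(30.0) == pytest.approx(23.93, abs=0.01)

    def test_equator_infinite(self):
        with pytest.warns(UserWarning, match="infinite"):
            assert dg.inertial_period(0.0) == np.inf

    def test_invalid_latitude(self):
        with pytest.raises(ValueError):
            dg.inertial_period(120.0)


def test_fraction_of():
    assert dg.fraction_of(1.0, 4.0) == 25.0
    assert dg.fraction_of(-1.0, 4.0) == 25.0
    assert dg.fraction_of(1.0, 4.0, percent=False) == 0.25
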