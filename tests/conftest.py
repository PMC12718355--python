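import numpy as np
import pytest

from stormflux import scenario as sc


@pytest.fixture(scope="session")
def scenario_result():
    """The canonical category-4 scenario, generated once per session."""
    cfg = sc.default_config(seed=7)
    return sc.generate_scenario(cfg, bookkeeping=("dic", "temperature"))


@pytest.fixture(scope="session")
def hurricane_truth(scenario_result):
    """Planted track points at hurricane strength, 6-hourly."""
    truth = scenario_result.truth.tracks
    return truth[truth.vmax_ms > 33].iloc[::6]


@pytest.fixture()
def small_config():
    """A light, fast scenario for determinism and CLI tests."""
    # spacing must stay below the 100-km stitching radius (~0.9 deg)
    cfg = sc.default_config(seed=11, spacing_deg=0.75, n_hours=168)
    t0 = np.datetime64(cfg.start_time, "s")

    def h(hours):
        return t0 + np.timedelta64(int(hours * 3600), "s")

    cfg.vortices = [dict(
        waypoints=[(h(24), 20.0, -62.0), (h(120), 30.0, -66.0)],
        vmax_ramp=[(h(24), 18.0), (h(48), 48.0), (h(96), 48.0),
                   (h(120), 25.0)],
        r_mw_km=50.0)]
    return cfg
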