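import numpy as np
import pandas as pd
import pytest

from mvftrack import (GpsFixSeries, MvfConfig, SyntheticScenario,
                      run_pipeline, simulate_scenario)


@pytest.fixture(scope="session")
def small_run():
    """One 2 h default-calibration scenario, simulated and filtered."""
    sc = SyntheticScenario(duration=7200, seed=1)
    gps, accel, truth = simulate_scenario(sc)
    track = run_pipeline(gps, accel, MvfConfig())
    return {"scenario": sc, "gps": gps, "accel": accel,
            "truth": truth, "track": track}


def make_fixes(lat, lon, t0=0, missing=None):
    """GpsFixSeries on a 1 s grid from coordinate arrays (NaN = missing)."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if missing is None:
        missing = ~np.isfinite(lat)
    return GpsFixSeries(np.arange(t0, t0 + len(lat)), lat, lon,
                        np.asarray(missing, dtype=bool))


@pytest.fixture
def fixes_factory():
    return make_fixes


def make_track(vedba, speed, lat=None, t0=0):
    """Aligned-track frame with constant position unless given."""
    n = len(vedba)
    if lat is None:
        lat = np.zeros(n)
    return pd.DataFrame({
        "time": np.arange(t0, t0 + n),
        "lat": lat,
        "lon": np.zeros(n),
        "vedba": np.asarray(vedba, dtype=float),
        "speed": np.asarray(speed, dtype=float),
    })


@pytest.fixture
def track_factory():
    return make_track
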