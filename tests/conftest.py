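import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import aisfish as af

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_fleet() -> af.FleetData:
    """A compact fleet reused across read-only tests."""
    return af.simulate_fleet(af.SimConfig(n_vessels=8, trips_per_vessel=3, seed=11))


@pytest.fixture(scope="session")
def default_fleet() -> af.FleetData:
    """The default study conditions: 30 vessels, 4 trips each."""
    return af.simulate_fleet(af.SimConfig(seed=5))


@pytest.fixture(scope="session")
def default_pipeline(default_fleet):
    """Cleaned, fitted and labeled messages for the default fleet."""
    cleaned, ledger = af.clean_messages(default_fleet.messages)
    labeled, params = af.fit_and_classify_fleet(cleaned, seed=0)
    return dict(cleaned=cleaned, ledger=ledger, labeled=labeled, params=params)


def straight_track(n: int, lat: float = 57.5, lon0: float = 10.0,
                   dlon: float = 0.005, speed: float = 8.0,
                   vessel: str = "V1", t0: str = "2024-03-01T00:00:00Z",
                   step_s: int = 300) -> pd.DataFrame:
    """A constant-speed east-west track at fixed cadence, for fixtures."""
    times = pd.date_range(t0, periods=n, freq=f"{step_s}s")
    return pd.DataFrame(dict(
        ais_vessel_id=vessel, timestamp=times, lat=lat,
        lon=lon0 + dlon * np.arange(n), speed=speed))
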