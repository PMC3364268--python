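import numpy as np
import pandas as pd
import pytest

from marshpulse import run_all
from marshpulse.hydrology import PulseWindow, WaterLevelSeries


def make_series(stages, area="test", elev=0.0, start="2005-02-01"):
    """Hourly WaterLevelSeries from a list of stage values (mm)."""
    stages = np.asarray(stages, dtype=float)
    times = pd.date_range(start, periods=len(stages), freq="h")
    return WaterLevelSeries(area, elev, times, stages)


@pytest.fixture(scope="session")
def default_result():
    """One full default-configuration run shared across tests."""
    return run_all(seed=1)


@pytest.fixture()
def two_day_window():
    return PulseWindow("toy", pd.Timestamp("2005-02-01"),
                       pd.Timestamp("2005-02-03"))
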