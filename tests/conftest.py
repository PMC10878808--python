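import numpy as np
import pandas as pd
import pytest

from nestrec.synthetic import GeneratorParams, simulate_study
from nestrec.timeseries_io import TemperatureTrace

START = pd.Timestamp("2019-06-20 00:00")


@pytest.fixture(scope="session")
def small_bundle():
    """A small but fully-featured synthetic study (shared, read-only)."""
    return simulate_study(GeneratorParams(n_nests=8, days_per_nest=6), seed=11)


@pytest.fixture()
def flat_trace():
    """Constant 38 degC nest trace, two days, no recesses."""

    def make(n_minutes=2880, temp=38.0, nest_id="NX"):
        return TemperatureTrace(
            logger_id="L1",
            nest_id=nest_id,
            site="SYN",
            start=START,
            temps=np.full(n_minutes, temp),
        )

    return make


def plant_dip(temps, start, duration, depth):
    """Rectangular temperature dip (in place) and return the slice."""
    temps[start : start + duration] = temps[start] - depth
    return temps
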