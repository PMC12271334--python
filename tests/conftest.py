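from datetime import datetime, timedelta

import numpy as np
import pytest

from ppgv.core_io import FOOD_GROUPS, GlucoseSeries, MealEvent


def make_series(values, start="2021-03-01T08:00", step_min=15.0, pid="P1"):
    """GlucoseSeries from a plain list, evenly sampled."""
    t0 = np.datetime64(start, "ns")
    ts = t0 + (np.arange(len(values)) * step_min * 60e9).astype("timedelta64[ns]")
    return GlucoseSeries(pid, ts, np.asarray(values, dtype=float), nominal_interval=step_min)


def make_meal(timestamp, pid="P1", raw_text=None, **grams):
    g = {grp: 0.0 for grp in FOOD_GROUPS}
    g.update(grams)
    return MealEvent(pid, timestamp, g, sum(v for v in g.values() if not np.isnan(v)), raw_text=raw_text)


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def meal_factory():
    return make_meal
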