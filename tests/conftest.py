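import numpy as np
import pandas as pd
import pytest

from ventrhythms.series_prep import HourlySeries

START = pd.Timestamp("2011-10-07 08:00", tz="UTC")


def make_series(values, start=START, **kw) -> HourlySeries:
    """HourlySeries from a plain value list (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    grid = pd.date_range(start, periods=len(values), freq="h")
    return HourlySeries(grid, values, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20111007)
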