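import numpy as np
import pytest

from d9assess.datamodel import SampleRecord, SeriesKey, TimeSeries


def make_series(years, values, censored=None, analyte="Pb", site="NS1",
                species="Mytilus edulis", tissue="soft body", unit="mg/kg",
                basis="wet") -> TimeSeries:
    censored = censored or [False] * len(years)
    key = SeriesKey(site, species, tissue, analyte, basis, unit)
    return TimeSeries(key=key, points=list(zip(years, values, censored)))


@pytest.fixture
def line_series():
    """12 annual values exactly on a declining straight line."""
    years = list(range(2000, 2012))
    values = [10.0 - 0.5 * (y - 2000) for y in years]
    return make_series(years, values)


@pytest.fixture
def noisy_decline_series():
    """Seeded exponential decline with mild lognormal noise, 20 years."""
    rng = np.random.default_rng(42)
    years = list(range(1998, 2018))
    mean = 8.0 * np.exp(-0.08 * (np.arange(20)))
    values = mean * rng.lognormal(-0.005, 0.1, 20)
    return make_series(years, list(values))


@pytest.fixture
def demo_records():
    from d9assess.synthetic import demo_dataset

    records, contexts = demo_dataset(seed=123)
    return records, contexts
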