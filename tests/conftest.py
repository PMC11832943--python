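import numpy as np
import pytest

from dendrotrend.ringio import RingSeries
from dendrotrend.synthetic import StandParams, simulate_climate, simulate_stand


@pytest.fixture()
def toy_series() -> RingSeries:
    return RingSeries(series_id="TOY1a", tree_id="TOY1", first_year=1950,
                      widths=np.array([1.0, 2.0, 3.0, 2.0, 1.0, 2.0]))


@pytest.fixture(scope="session")
def default_stand():
    """One default synthetic stand (seed 1): cores, records, ground truth."""
    params = StandParams(seed=1)
    years = range(params.first_year - 2, params.end_year + 1)
    stations = simulate_climate(years, params)
    cores, records, truth = simulate_stand(params, stations)
    return params, stations, cores, records, truth
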