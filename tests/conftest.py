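import json

import numpy as np
import pytest

from specplot import DataSeries, DataSet, Point, parse_series
from specplot.fixtures import make_molfiles, make_ms_peaks, make_nmr_trace


@pytest.fixture(scope="session")
def molfile_corpus():
    return make_molfiles()


@pytest.fixture()
def ms_series():
    """A seeded 40-peak mass spectrum series."""
    return parse_series(json.dumps(make_ms_peaks(seed=7)), kind="peaks")


@pytest.fixture()
def ms_dataset(ms_series):
    return DataSet().add(ms_series)


@pytest.fixture(scope="session")
def nmr_trace_60k():
    """A seeded 60,000-point 1D NMR trace series."""
    return parse_series(json.dumps(make_nmr_trace(seed=11, n_points=60000)), kind="trace")


def random_series(rng, n, clustered=False):
    """Random sorted point list; x uniform or clustered around a few centers."""
    if clustered and n >= 4:
        k = int(rng.integers(2, 6))
        centers = rng.uniform(0.0, 100.0, size=k)
        xs = rng.normal(centers[rng.integers(0, k, size=n)], 1.5)
    else:
        xs = rng.uniform(0.0, 100.0, size=n)
    xs = np.sort(xs)
    ys = rng.normal(0.0, 10.0, size=n)
    return [Point(float(x), float(y)) for x, y in zip(xs, ys)]
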