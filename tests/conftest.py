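import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mitofast.synthetic_data import LineSpec, fig1e_like_spec, make_flow_mixture, make_vertex_table


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fig1e_events():
    """Canonical segregated-population event table with planted Fig 1E-type fractions."""
    spec = fig1e_like_spec(0.509, 0.0332, 0.458, n_events=10_000, seed=20)
    return make_flow_mixture(spec)


@pytest.fixture
def straight_line_table():
    """One straight 11-point line at 0.5 um spacing: total length 5.0 um."""
    return make_vertex_table(
        [LineSpec(n_points=11, spacing=0.5)], channels={"ch1": 10.0, "ch2": 10.0}
    )


@pytest.fixture
def random_polyline_table(rng):
    """A jagged 3-D polyline with coordinates perturbed off a straight path."""
    n = 200
    pts = np.cumsum(rng.normal(0.0, 0.3, size=(n, 3)), axis=0)
    return pd.DataFrame(
        {
            "line_id": 0,
            "point_id": np.arange(n),
            "x": pts[:, 0],
            "y": pts[:, 1],
            "z": pts[:, 2],
            "tmrm": rng.uniform(1, 100, n),
            "mtng": rng.uniform(1, 100, n),
        }
    )
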