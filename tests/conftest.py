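import numpy as np
import pytest

import contrafc as cf


@pytest.fixture
def toy_table() -> cf.ROITable:
    """Four ROIs, two per hemisphere, two networks."""
    return cf.ROITable(
        records=(
            cf.ROIRecord("roi1", -32.0, 10.0, 4.0, "Default Mode"),
            cf.ROIRecord("roi2", -20.0, -60.0, 40.0, "Visual"),
            cf.ROIRecord("roi3", 32.0, 10.0, 4.0, "Default Mode"),
            cf.ROIRecord("roi4", 20.0, -60.0, 40.0, "Visual"),
        ),
        provenance="toy",
    )


@pytest.fixture
def small_params() -> cf.SimulationParams:
    """A 15-ROI-per-hemisphere generator for fast unit tests."""
    return cf.SimulationParams(
        n_per_hemisphere=15,
        network_sizes={"SDN": 4, "FPN": 3, "SN": 3, "DAN": 2},
        n_frames=120,
        n_runs=2,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_symmetric_unit_diag(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random symmetric matrix with unit diagonal and entries in [-1, 1]."""
    a = rng.uniform(-1.0, 1.0, size=(n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a
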