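import numpy as np
import pytest

import pactcal as pc


@pytest.fixture
def c_water() -> pc.SoundSpeed:
    return pc.SoundSpeed.from_m_per_s(1500.0)


@pytest.fixture
def tetra_grid() -> pc.PointSourceGrid:
    """Four affinely independent sources (full-rank pairwise system)."""
    return pc.PointSourceGrid(
        np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    )


@pytest.fixture
def ring_geometry() -> pc.ArrayGeometry:
    return pc.make_array_geometry("ring", radius=100.0, n_elements=64)


@pytest.fixture
def stage_grid() -> pc.PointSourceGrid:
    return pc.PointSourceGrid.regular((4, 4, 3), 2.0, center=True)


def analytic_toas(positions, grid, c) -> pc.ToAMatrix:
    """Noise-free model arrival times for every (source, transducer) pair."""
    times = np.array([pc.predict_toa(p, grid.positions, c) for p in positions]).T
    return pc.ToAMatrix(times)
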