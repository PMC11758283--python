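import numpy as np
import pytest

from trsfx.core import (
    BeamConfig,
    MillerIndexSet,
    Snapshot,
    SnapshotSeries,
    UnitCell,
    build_index_set,
)


@pytest.fixture
def cubic_cell():
    return UnitCell(10.0, 10.0, 10.0)


@pytest.fixture
def hex_cell():
    return UnitCell(66.9, 66.9, 40.8, 90.0, 90.0, 120.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_index_set(cubic_cell):
    """Cubic a=10, d_min=2.5: a few hundred reflections."""
    return build_index_set(cubic_cell, 2.5)


@pytest.fixture
def tiny_index_set(cubic_cell):
    return build_index_set(cubic_cell, 5.0)


def make_series(index_set, cell, intensities, timestamps=None, beam=None, rng=None):
    """Helper: a fully observed snapshot series (p = 1, identity quats)."""
    D, N = intensities.shape
    beam = beam or BeamConfig(9.5, 0.01)
    snaps = []
    for j in range(N):
        snaps.append(
            Snapshot(
                timestamp=float(j if timestamps is None else timestamps[j]),
                orientation=np.array([1.0, 0.0, 0.0, 0.0]),
                rows=np.arange(D),
                intensity=intensities[:, j].copy(),
                partiality=np.ones(D),
            )
        )
    return SnapshotSeries(snaps, index_set, cell, beam)


@pytest.fixture
def make_full_series():
    return make_series
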