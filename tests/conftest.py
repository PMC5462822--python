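import numpy as np
import pytest

from endemap.core_data import (
    GridSpec,
    OccurrenceRecord,
    PresenceAbsenceMatrix,
    build_presence_matrix,
    filter_cells_by_records,
    records_from_dataframe,
)
from endemap.raster import RasterGeometry
from endemap.synthetic import generate_preset


@pytest.fixture(scope="session")
def amazon_grid():
    return GridSpec(-70.0, -15.0, -50.0, 5.0, 1.0)


@pytest.fixture(scope="session")
def amazon_raster():
    return RasterGeometry(-70.0, -15.0, -50.0, 5.0, 0.1)


@pytest.fixture(scope="session")
def three_aoes_data():
    """Occurrences + truth for the planted three-areas preset (default seed)."""
    return generate_preset("three_aoes")


@pytest.fixture(scope="session")
def one_river_data():
    return generate_preset("one_river")


@pytest.fixture(scope="session")
def one_river_pam(one_river_data, amazon_grid):
    df, _ = one_river_data
    pam = build_presence_matrix(records_from_dataframe(df), amazon_grid)
    return filter_cells_by_records(pam, 10)


def random_pam(rng, n_cells=20, n_taxa=50, p=0.3) -> PresenceAbsenceMatrix:
    """A random binary matrix with every cell occupied (helper, not a fixture)."""
    grid = GridSpec(0.0, 0.0, float(n_cells), 1.0, 1.0)
    while True:
        m = (rng.random((n_cells, n_taxa)) < p).astype(np.uint8)
        if (m.sum(axis=1) > 0).all() and (m.sum(axis=0) > 0).all():
            break
    return PresenceAbsenceMatrix(
        grid, [f"t{j}" for j in range(n_taxa)], np.arange(n_cells), m,
        np.full(n_cells, 20),
    )
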