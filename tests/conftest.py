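import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from centriole_polarity import (
    SimulationConfig,
    assign_centrioles,
    extract_cell_geometries,
    generate_epithelium,
)

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_square_mask(side=10, origin=(1, 1), pad=2, label=1):
    """Label mask holding one square cell of `side` px with background margin."""
    oy, ox = origin[1], origin[0]
    mask = np.zeros((side + oy + pad, side + ox + pad), dtype=np.uint16)
    mask[oy : oy + side, ox : ox + side] = label
    return mask


@pytest.fixture(scope="session")
def square_mask():
    return make_square_mask(side=10, origin=(1, 1))


@pytest.fixture(scope="session")
def small_field():
    """50-cell synthetic epithelium (seed 7), the shared small fixture."""
    cfg = SimulationConfig(n_cells_x=10, n_cells_y=5, seed=7)
    return cfg, *generate_epithelium(cfg)


@pytest.fixture(scope="session")
def scored_small(small_field):
    _, mask, table, truth = small_field
    cells = extract_cell_geometries(mask)
    records, unassigned = assign_centrioles(
        mask, cells, list(zip(table["x"], table["y"]))
    )
    return mask, cells, records, unassigned, truth
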