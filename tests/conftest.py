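import numpy as np
import pytest
from shapely.geometry import Polygon

from capouch import ModelParameters, generate_tissue


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def small_tissue():
    return generate_tissue(60, lloyd_iterations=3, seed=11)


def hexagon(cx, cy, side):
    ang = np.pi / 6 + np.arange(6) * np.pi / 3
    return Polygon(np.column_stack([cx + side * np.cos(ang),
                                    cy + side * np.sin(ang)]))


@pytest.fixture(scope="session")
def hex_lattice():
    """5x5 block of regular hexagons with side 1 (flat-top row packing)."""
    side = 1.0
    dx = np.sqrt(3) * side
    dy = 1.5 * side
    cells = []
    for row in range(5):
        for col in range(5):
            cx = col * dx + (row % 2) * dx / 2
            cells.append(hexagon(cx, row * dy, side))
    return cells
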