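import numpy as np
import pytest

from memtopo import surfaces


@pytest.fixture(scope="session")
def flat9():
    return surfaces.build_flat(9, 9)


@pytest.fixture(scope="session")
def ridged_small():
    """Two-and-a-bit periods of the folded h4/w4/s2 ridge field."""
    return surfaces.build_ridges((26, 17), 4, 4, 2, phase=2)


@pytest.fixture(scope="session")
def deformed_small():
    """A small deformed surface (degrees 3, 4 and 5 present)."""
    return surfaces.build_from_height_map(
        np.array(
            [
                [0, 0, 0, 0, 0],
                [0, 2, 2, 0, 1],
                [0, 2, 2, 0, 0],
                [0, 0, 0, 3, 0],
                [1, 0, 0, 0, 0],
            ]
        )
    )


@pytest.fixture(scope="session")
def star_graph():
    """Plus-shaped 5-node graph: hub of degree 4, four leaves of degree 1."""
    return surfaces.SurfaceGraph([(1, 1, 0), (0, 1, 0), (2, 1, 0), (1, 0, 0), (1, 2, 0)])
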