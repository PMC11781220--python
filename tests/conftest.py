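import numpy as np
import pytest

from dftomo.mesh import FiberConfig, TetMesh, build_box_mesh


@pytest.fixture(scope="session")
def unit_tet():
    """Single tetrahedron of volume 1 cm^3 (1000 mm^3)."""
    nodes = np.array(
        [[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [0.0, 10.0, 0.0], [0.0, 0.0, 60.0]]
    )
    return TetMesh(nodes, np.array([[0, 1, 2, 3]]))


@pytest.fixture(scope="session")
def two_tets():
    """Two tetrahedra sharing the face (0,1,2)."""
    nodes = np.array(
        [
            [0.0, 0.0, 0.0],
            [10.0, 0.0, 0.0],
            [0.0, 10.0, 0.0],
            [0.0, 0.0, 10.0],
            [0.0, 0.0, -20.0],
        ]
    )
    return TetMesh(nodes, np.array([[0, 1, 2, 3], [0, 1, 2, 4]]))


@pytest.fixture(scope="session")
def small_box():
    """Uniform ~350-node mesh of a 1 cm^3 box."""
    return build_box_mesh((10.0, 10.0, 10.0), None, target_nodes=300, seed=0)


@pytest.fixture(scope="session")
def four_fiber_cfg():
    return FiberConfig(
        np.array(
            [[8.0, 10.0, 10.0], [12.0, 10.0, 10.0], [10.0, 8.0, 11.0], [10.0, 12.0, 9.0]]
        )
    )


@pytest.fixture(scope="session")
def fiber_box(four_fiber_cfg):
    """Small graded mesh around four interstitial fibers (20 mm box)."""
    return build_box_mesh(
        (20.0, 20.0, 20.0), four_fiber_cfg, target_nodes=900, refine_radius=2.5, seed=0
    )
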