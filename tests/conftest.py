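import numpy as np
import pytest

from vesselfe.materials import OgdenPronyMaterial, VesselMaterial
from vesselfe.meshing import BeamMesh, voxelize
from vesselfe.synthetic import VesselNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tissue():
    return OgdenPronyMaterial()


@pytest.fixture
def vessel():
    return VesselMaterial()


@pytest.fixture
def small_network():
    """Hand-built 4-node, 3-segment Y-shaped network (µm)."""
    return VesselNetwork(
        nodes=[[100, 100, 100], [200, 100, 100], [260, 160, 100], [260, 40, 100]],
        radii=[10.0, 8.0, 6.0, 5.0],
        segments=[[0, 1], [1, 2], [1, 3]],
    )


@pytest.fixture
def cube_mesh():
    """6x6x6 block of 50 µm voxel elements."""
    return voxelize(np.ones((6, 6, 6), dtype=bool), 50.0, 1)


@pytest.fixture
def centre_beams():
    """A few beams around the centre of the 300 µm cube mesh."""
    nodes = np.array(
        [
            [120.0, 150.0, 150.0],
            [180.0, 150.0, 150.0],
            [150.0, 120.0, 180.0],
            [150.0, 180.0, 120.0],
        ]
    )
    return BeamMesh(
        nodes=nodes,
        radii=np.full(4, 5.0),
        elements=np.array([[0, 1], [2, 3]]),
    )
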