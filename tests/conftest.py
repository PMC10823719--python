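import numpy as np
import pytest
import trimesh

from mandisym.alignment import SurfaceDistanceQuery
from mandisym.synthetic import generate_mandible


@pytest.fixture(scope="session")
def mandible():
    """Default exactly-symmetric synthetic mandible: (mesh, landmarks, plane)."""
    return generate_mandible()


@pytest.fixture(scope="session")
def mandible_query(mandible):
    mesh, _, _ = mandible
    return SurfaceDistanceQuery(mesh)


@pytest.fixture(scope="session")
def unit_cube():
    """Closed unit cube [0, 1]^3."""
    cube = trimesh.creation.box(extents=(1, 1, 1))
    cube.apply_translation([0.5, 0.5, 0.5])
    return cube


@pytest.fixture(scope="session")
def icosphere():
    """Subdivided icosphere, radius 10 mm (convex, so hull volume is an oracle)."""
    return trimesh.creation.icosphere(subdivisions=4, radius=10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240129)
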