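import numpy as np
import pytest
import trimesh

from gpsa import TriangleMesh

TETRA_VERTICES = np.array(
    [
        [0.0, 0.0, 0.0],
        [1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0],
    ]
)
TETRA_FACES = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])


@pytest.fixture
def tetra() -> TriangleMesh:
    return TriangleMesh(TETRA_VERTICES.copy(), TETRA_FACES.copy(), name="tetra")


@pytest.fixture
def icosphere():
    def make(subdivisions: int = 2, radii=(1.0, 1.0, 1.0), name="ico") -> TriangleMesh:
        ico = trimesh.creation.icosphere(subdivisions=subdivisions)
        v = np.asarray(ico.vertices) * np.asarray(radii, float)
        return TriangleMesh(v, np.asarray(ico.faces), name=name)

    return make


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, max_deg))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
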