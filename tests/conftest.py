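import numpy as np
import pytest

from limbmorph.geometry import TriMesh
from limbmorph.shape_model import build_ssm
from limbmorph.synthetic import SyntheticSpec, generate_population


@pytest.fixture()
def cube_mesh() -> TriMesh:
    """Unit cube: 8 vertices, 12 triangles."""
    v = np.array(
        [[x, y, z] for x in (0.0, 1.0) for y in (0.0, 1.0) for z in (0.0, 1.0)]
    )
    t = np.array(
        [
            [0, 1, 3], [0, 3, 2],
            [4, 6, 7], [4, 7, 5],
            [0, 4, 5], [0, 5, 1],
            [2, 3, 7], [2, 7, 6],
            [0, 2, 6], [0, 6, 4],
            [1, 5, 7], [1, 7, 3],
        ]
    )
    return TriMesh(v, t)


@pytest.fixture(scope="session")
def small_population():
    """Coarse 8-subject synthetic population shared across tests."""
    spec = SyntheticSpec(n_subjects=8, seed=7, n_axial=24, n_circ=12)
    return generate_population(spec)


@pytest.fixture(scope="session")
def small_ssm(small_population):
    return build_ssm([s.mesh for s in small_population], align=False)
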