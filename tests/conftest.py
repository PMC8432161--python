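import numpy as np
import pytest

from lesionplan.surface_io import HemisphereSurface
from lesionplan.synthetic_data import (SyntheticCohortSpec, icosphere,
                                       make_cohort, make_hemisphere_pair)


def build_icosahedron(radius: float = 1.0) -> HemisphereSurface:
    verts, faces = icosphere(0, radius)
    return HemisphereSurface(verts, faces)


def build_planar_grid(n: int = 15, spacing: float = 1.0) -> HemisphereSurface:
    """Flat triangulated square grid (with diagonals) in the z=0 plane."""
    xs, ys = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing,
                         indexing="ij")
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])
    tris = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b = a + 1
            c = a + n
            d = c + 1
            tris += [[a, b, d], [a, d, c]]
    return HemisphereSurface(verts, np.asarray(tris))


@pytest.fixture(scope="session")
def icosahedron():
    return build_icosahedron()


@pytest.fixture(scope="session")
def sphere_mesh():
    verts, faces = icosphere(3, 20.0)
    return HemisphereSurface(verts, faces)


@pytest.fixture(scope="session")
def fine_sphere_mesh():
    verts, faces = icosphere(4, 25.0)
    return HemisphereSurface(verts, faces)


@pytest.fixture(scope="session")
def planar_grid():
    return build_planar_grid(n=15)


@pytest.fixture(scope="session")
def hemisphere_pair():
    return make_hemisphere_pair(3)


@pytest.fixture(scope="session")
def small_cohort():
    """Small synthetic cohort (subdivision 3) shared across tests."""
    spec = SyntheticCohortSpec(n_patients=4, n_controls=6, subdivision=3,
                               seed=11)
    return make_cohort(spec)
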