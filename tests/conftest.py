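import numpy as np
import pytest

from activedrop import geometry
from activedrop._fem import DirichletPoisson, FemSpaces


@pytest.fixture(scope="session")
def semicircle():
    return geometry.initial_semicircle(64)


@pytest.fixture(scope="session")
def coarse_curve():
    # spacing ~ 0.1 for the cheap meshes used in most unit tests
    return geometry.initial_semicircle(33)


@pytest.fixture(scope="session")
def coarse_mesh(coarse_curve):
    return geometry.build_mesh(coarse_curve, 0.1, seed=0)


@pytest.fixture(scope="session")
def coarse_spaces(coarse_mesh):
    return FemSpaces(coarse_mesh)


@pytest.fixture(scope="session")
def coarse_poisson(coarse_spaces):
    return DirichletPoisson(coarse_spaces)


@pytest.fixture(scope="session")
def default_mesh(semicircle):
    # the resolution used for the headline results
    return geometry.build_mesh(semicircle, 0.05, seed=0)


def square_mesh(n=8):
    """Structured triangulation of the unit square (plain DropMesh container
    without the drop-specific boundary, for quadrature/operator tests)."""
    xs = np.linspace(0.0, 1.0, n + 1)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])
    tris = []
    for i in range(n):
        for j in range(n):
            v00 = i * (n + 1) + j
            v10 = (i + 1) * (n + 1) + j
            tris.append([v00, v10, v00 + 1])
            tris.append([v10, v10 + 1, v00 + 1])
    tris = np.array(tris)
    on_b = (np.isclose(pts[:, 0], 0) | np.isclose(pts[:, 0], 1)
            | np.isclose(pts[:, 1], 0) | np.isclose(pts[:, 1], 1))
    # boundary edges: consecutive boundary vertices along the four sides
    edges = []
    for tri in tris:
        for a, b in ((0, 1), (1, 2), (2, 0)):
            edges.append(tuple(sorted((tri[a], tri[b]))))
    from collections import Counter
    cnt = Counter(edges)
    bedges = np.array([e for e, c in cnt.items() if c == 1])
    tags = np.where(np.all(np.isclose(pts[bedges][:, :, 1], 0), axis=1), 0, 1)
    return geometry.DropMesh(points=pts, triangles=tris,
                             boundary_edges=bedges, boundary_tags=tags,
                             h_mesh=1.0 / n)
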