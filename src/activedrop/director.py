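"""Quasi-static polarized director field with winding-number anchoring.

In the strong elastic limit the orientation field relaxes instantaneously to
the minimum of the one-constant Frank energy, which makes each Cartesian
component of p harmonic (componentwise Laplace equation) with Dirichlet
anchoring data.  The anchoring is a quarter-turn rotation of the boundary
tangent: p = R(w_i pi/2) t_hat on the liquid-air interface and
p = R(w_s pi/2) e_x on the substrate, with counterclockwise rotations for
positive winding numbers.

No unit-norm constraint is applied in the bulk: |p| <= 1 by the maximum
principle, and |p| dips at defects, which naturally regularizes the active
stress there.  Boundary anchoring mismatches at the contact points produce
the boundary point defects of the bipolar configuration; a 90-degree
mismatch bottoms out at |p| -> 1/sqrt(2), while a 180-degree mismatch (e.g.
w_s=0, w_i=1 at the left contact) forces |p| -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry
from ._fem import DirichletPoisson, FemSpaces

__all__ = ["AnchoringSpec", "DirectorField", "boundary_director",
           "solve_director", "defect_census", "rotation"]

#: default |p| threshold below which a local minimum counts as a defect;
#: sits above the 1/sqrt(2) floor of 90-degree boundary defects and below
#: the shallowest smooth-field features (~0.93 on the reference half-disk)
DEFECT_THRESHOLD = 0.8


def rotation(quarter_turns: int) -> np.ndarray:
    """Counterclockwise rotation matrix by ``quarter_turns * pi/2``."""
    a = quarter_turns * np.pi / 2.0
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class AnchoringSpec:
    """Winding numbers of the boundary anchoring (quarter turns CCW relative
    to the boundary tangent: e_x at the substrate, t_hat at the interface)."""

    w_s: int
    w_i: int

    def __post_init__(self):
        object.__setattr__(self, "w_s", int(self.w_s) % 4)
        object.__setattr__(self, "w_i", int(self.w_i) % 4)
        if self.w_s not in (0, 1):
            raise ValueError(
                f"w_s={self.w_s}: substrate anchoring must be planar (0) "
                "or homeotropic (1)")

    @property
    def theta_s(self) -> float:
        return self.w_s * np.pi / 2.0

    @property
    def theta_i(self) -> float:
        return self.w_i * np.pi / 2.0


@dataclass
class DirectorField:
    """Per-vertex director p on a :class:`~activedrop.geometry.DropMesh`."""

    p: np.ndarray        # (n_vertices, 2)
    mesh: object = None

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.p, axis=1)

    def normalized(self, floor: float = 0.1) -> "DirectorField":
        """p / max(|p|, floor) -- optional sensitivity variant."""
        mag = np.maximum(self.magnitude, floor)
        return DirectorField(self.p / mag[:, None], self.mesh)

    def tensor_pp(self) -> np.ndarray:
        """(n, 2, 2) outer products p p used by the active stress."""
        return np.einsum("ni,nj->nij", self.p, self.p)


def boundary_director(mesh: geometry.DropMesh, curve: geometry.InterfaceCurve,
                      anchoring: AnchoringSpec) -> np.ndarray:
    """Dirichlet director data, aligned with ``mesh.boundary_vertices``.

    Substrate vertices get ``R(w_s pi/2) e_x``; interface vertices get
    ``R(w_i pi/2) t_hat`` with the tangent taken from the current curve; the
    two contact-point vertices receive the substrate value (precedence rule,
    the anchoring mismatch being absorbed by the graded mesh).
    """
    bv = mesh.boundary_vertices
    values = np.zeros((bv.size, 2))
    pos = {v: k for k, v in enumerate(bv)}

    t_hat, _, _ = geometry.frame_and_curvature(curve)
    Ri = rotation(anchoring.w_i)
    seg = mesh.interface_param[:, 0].astype(int)
    tau = mesh.interface_param[:, 1]
    t_interp = (1.0 - tau)[:, None] * t_hat[seg] + tau[:, None] * t_hat[
        np.minimum(seg + 1, curve.n - 1)]
    t_interp /= np.linalg.norm(t_interp, axis=1)[:, None]
    p_int = t_interp @ Ri.T
    for v, p in zip(mesh.interface_vertices, p_int):
        values[pos[v]] = p

    p_sub = rotation(anchoring.w_s) @ np.array([1.0, 0.0])
    for v in mesh.substrate_vertices:   # includes corners -> precedence
        values[pos[v]] = p_sub
    return values


def solve_director(mesh: geometry.DropMesh, bc: np.ndarray,
                   poisson: DirichletPoisson | None = None) -> DirectorField:
    """Componentwise harmonic extension of the boundary director data.

    ``bc`` is aligned with ``mesh.boundary_vertices``.  The factorized
    Poisson solver may be passed in to share it across solves on one mesh.
    """
    if poisson is None:
        poisson = DirichletPoisson(FemSpaces(mesh))
    bc = np.asarray(bc, float)
    if bc.shape != (mesh.boundary_vertices.size, 2):
        raise ValueError("bc must cover all boundary vertices (nb, 2)")
    px = poisson.solve(bc[:, 0])
    py = poisson.solve(bc[:, 1])
    return DirectorField(np.column_stack([px, py]), mesh)


def defect_census(field: DirectorField, mesh: geometry.DropMesh,
                  threshold: float = DEFECT_THRESHOLD):
    """Local minima of |p| below ``threshold``, merged within ``2 h_mesh``.

    Returns a list of ``(location, |p|)`` tuples sorted by depth (deepest
    first).  Orientation singularities pinned at the boundary (the bipolar
    contact-point defects) are shallow minima with |p| near 1/sqrt(2), so
    the default threshold sits above that level.
    """
    if not 0.0 < threshold:
        raise ValueError("threshold must be positive")
    mag = field.magnitude
    # vertex adjacency from triangles; the two-ring minimum test filters
    # out the shallow one-ring minima that mesh grading produces in steep
    # parts of the field
    tris = mesh.triangles
    nbr_min = np.full(mag.size, np.inf)
    for a, b in ((0, 1), (1, 2), (2, 0)):
        np.minimum.at(nbr_min, tris[:, a], mag[tris[:, b]])
        np.minimum.at(nbr_min, tris[:, b], mag[tris[:, a]])
    ring1 = np.minimum(nbr_min, mag)
    nbr2_min = np.full(mag.size, np.inf)
    for a, b in ((0, 1), (1, 2), (2, 0)):
        np.minimum.at(nbr2_min, tris[:, a], ring1[tris[:, b]])
        np.minimum.at(nbr2_min, tris[:, b], ring1[tris[:, a]])
    is_min = (mag <= nbr2_min) & (mag < threshold)
    cand = np.where(is_min)[0]
    cand = cand[np.argsort(mag[cand])]
    kept: list[tuple[np.ndarray, float]] = []
    merge_r = 2.0 * mesh.h_mesh
    for v in cand:
        pt = mesh.points[v]
        if all(np.linalg.norm(pt - loc) > merge_r for loc, _ in kept):
            kept.append((pt.copy(), float(mag[v])))
    return kept
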