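"""Minimal finite-element kernels on triangles: P1 and P2 Lagrange spaces.

Vectorized (einsum) assembly of the operators the drop model needs:

* P1 stiffness/mass for the harmonic director, the streamfunction and the
  Landau-de Gennes relaxation;
* Taylor-Hood (P2 velocity / P1 pressure) Stokes blocks, which is the
  standard inf-sup-stable pair needing no pressure stabilization;
* interface line integrals for the capillary traction;
* quadrature-exact evaluation of stress powers for the entropy rates.

Everything is assembled from a :class:`~activedrop.geometry.DropMesh`; the
P2 node set is the mesh vertices followed by the unique edge midpoints.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

# 6-point, degree-4 triangle quadrature (two symmetric orbits)
_A1, _W1 = 0.445948490915965, 0.223381589678011
_A2, _W2 = 0.091576213509771, 0.109951743655322
QUAD_BARY = np.array([
    [1 - 2 * _A1, _A1, _A1], [_A1, 1 - 2 * _A1, _A1], [_A1, _A1, 1 - 2 * _A1],
    [1 - 2 * _A2, _A2, _A2], [_A2, 1 - 2 * _A2, _A2], [_A2, _A2, 1 - 2 * _A2],
])
QUAD_W = np.array([_W1, _W1, _W1, _W2, _W2, _W2])

# 3-point Gauss-Legendre on [0, 1] (degree 5) for boundary edges
EDGE_Q = 0.5 + 0.5 * np.array([-np.sqrt(3.0 / 5.0), 0.0, np.sqrt(3.0 / 5.0)])
EDGE_W = 0.5 * np.array([5.0 / 9.0, 8.0 / 9.0, 5.0 / 9.0])


def _p2_ref(bary: np.ndarray):
    """P2 shape values and reference gradients at barycentric points.

    Local node order: vertices 0,1,2 then midpoints of edges (1,2), (2,0),
    (0,1).  Reference coordinates (xi, eta) with l0 = 1-xi-eta, l1 = xi,
    l2 = eta.
    """
    l0, l1, l2 = bary[:, 0], bary[:, 1], bary[:, 2]
    N = np.stack([l0 * (2 * l0 - 1), l1 * (2 * l1 - 1), l2 * (2 * l2 - 1),
                  4 * l1 * l2, 4 * l2 * l0, 4 * l0 * l1], axis=1)
    # d/dxi, d/deta of the l's: dl0 = (-1,-1), dl1 = (1,0), dl2 = (0,1)
    nq = bary.shape[0]
    dN = np.empty((nq, 6, 2))
    for q in range(nq):
        a, b, c = l0[q], l1[q], l2[q]
        dl = {0: np.array([-1.0, -1.0]), 1: np.array([1.0, 0.0]),
              2: np.array([0.0, 1.0])}
        dN[q, 0] = (4 * a - 1) * dl[0]
        dN[q, 1] = (4 * b - 1) * dl[1]
        dN[q, 2] = (4 * c - 1) * dl[2]
        dN[q, 3] = 4 * (c * dl[1] + b * dl[2])
        dN[q, 4] = 4 * (a * dl[2] + c * dl[0])
        dN[q, 5] = 4 * (b * dl[0] + a * dl[1])
    return N, dN


P2_N, P2_DN = _p2_ref(QUAD_BARY)          # (nq, 6), (nq, 6, 2)
P1_N = QUAD_BARY                           # (nq, 3)
P1_DN = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])  # (3, 2) constant


class FemSpaces:
    """P1/P2 node structure and per-element geometry for one mesh."""

    def __init__(self, mesh):
        self.mesh = mesh
        pts, tris = mesh.points, mesh.triangles
        self.n_p1 = pts.shape[0]
        # unique edges -> midpoint nodes
        raw = np.concatenate([tris[:, [1, 2]], tris[:, [2, 0]], tris[:, [0, 1]]])
        key = np.sort(raw, axis=1)
        edges, inv = np.unique(key, axis=0, return_inverse=True)
        self.edges = edges
        self.n_p2 = self.n_p1 + edges.shape[0]
        nt = tris.shape[0]
        self.tri6 = np.concatenate(
            [tris, self.n_p1 + inv.reshape(3, nt).T], axis=1)
        self.nodes_p2 = np.vstack(
            [pts, 0.5 * (pts[edges[:, 0]] + pts[edges[:, 1]])])
        # element geometry
        p0, p1, p2 = pts[tris[:, 0]], pts[tris[:, 1]], pts[tris[:, 2]]
        J = np.stack([p1 - p0, p2 - p0], axis=2)  # (nt, 2, 2), columns
        detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        self.area = 0.5 * detJ  # CCW triangles: positive
        Jinv = np.empty_like(J)
        Jinv[:, 0, 0] = J[:, 1, 1]
        Jinv[:, 0, 1] = -J[:, 0, 1]
        Jinv[:, 1, 0] = -J[:, 1, 0]
        Jinv[:, 1, 1] = J[:, 0, 0]
        Jinv /= detJ[:, None, None]
        self._JinvT = np.transpose(Jinv, (0, 2, 1))
        # physical gradients: P1 constant, P2 per quad point
        self.grad_p1 = np.einsum("eij,nj->eni", self._JinvT, P1_DN)
        self.grad_p2 = np.einsum("eij,qnj->qeni", self._JinvT, P2_DN)
        # edge midpoint lookup for boundary edges
        self._edge_index = {tuple(e): self.n_p1 + k
                            for k, e in enumerate(map(tuple, edges))}
        # substrate velocity dofs: substrate vertices + substrate edge midpoints
        sub = mesh.boundary_edges[mesh.boundary_tags == 0]
        dofs = set(np.unique(sub).tolist())
        for e in sub:
            dofs.add(self._edge_index[tuple(np.sort(e))])
        self.substrate_dofs_p2 = np.array(sorted(dofs), dtype=int)

    def midpoint_node(self, v0: int, v1: int) -> int:
        return self._edge_index[(min(v0, v1), max(v0, v1))]

    # -- scalar P1 operators ------------------------------------------------

    def stiffness_p1(self) -> sp.csr_matrix:
        tris = self.mesh.triangles
        Ke = np.einsum("eni,emi,e->enm", self.grad_p1, self.grad_p1, self.area)
        return _scatter(Ke, tris, tris, self.n_p1, self.n_p1)

    def mass_p1_lumped(self) -> np.ndarray:
        m = np.zeros(self.n_p1)
        np.add.at(m, self.mesh.triangles, (self.area / 3.0)[:, None])
        return m

    def load_p1(self, f_quad: np.ndarray) -> np.ndarray:
        """RHS vector from values of f at quadrature points, (nq, nt)."""
        Fe = np.einsum("qn,qe,q,e->en", P1_N, f_quad, QUAD_W, self.area)
        out = np.zeros(self.n_p1)
        np.add.at(out, self.mesh.triangles, Fe)
        return out

    # -- vector P2 / P1 Stokes blocks --------------------------------------

    def viscous_matrix(self) -> sp.csr_matrix:
        """2*n_p2 square block for int (grad u + grad u^T) : grad v."""
        t6 = self.tri6
        w = QUAD_W[:, None] * self.area[None, :]
        # E_ab[i,j] = int d_a phi_i d_b phi_j
        G = self.grad_p2  # (q, e, n, 2)
        Exx = np.einsum("qen,qem,qe->enm", G[..., 0], G[..., 0], w)
        Eyy = np.einsum("qen,qem,qe->enm", G[..., 1], G[..., 1], w)
        Exy = np.einsum("qen,qem,qe->enm", G[..., 0], G[..., 1], w)
        A11 = 2 * Exx + Eyy
        A22 = 2 * Eyy + Exx
        A12 = np.transpose(Exy, (0, 2, 1))  # int d_y phi_i d_x phi_j
        A21 = Exy
        n = self.n_p2
        blocks = [
            _scatter(A11, t6, t6, n, n), _scatter(A12, t6, t6, n, n),
            _scatter(A21, t6, t6, n, n), _scatter(A22, t6, t6, n, n),
        ]
        return sp.bmat([[blocks[0], blocks[1]], [blocks[2], blocks[3]]],
                       format="csr")

    def divergence_matrix(self) -> sp.csr_matrix:
        """(n_p1) x (2*n_p2) block for int q div u."""
        t6, t3 = self.tri6, self.mesh.triangles
        w = QUAD_W[:, None] * self.area[None, :]
        G = self.grad_p2
        Dx = np.einsum("qi,qem,qe->eim", P1_N, G[..., 0], w)
        Dy = np.einsum("qi,qem,qe->eim", P1_N, G[..., 1], w)
        n1, n2 = self.n_p1, self.n_p2
        return sp.bmat([[_scatter(Dx, t3, t6, n1, n2),
                         _scatter(Dy, t3, t6, n1, n2)]], format="csr")

    def active_rhs(self, T_quad: np.ndarray) -> np.ndarray:
        """int T : grad v for vector P2 test functions.

        ``T_quad``: (nq, nt, 2, 2) tensor values at quadrature points.
        Returns a (2*n_p2,) vector ordered [x-dofs, y-dofs].
        """
        w = QUAD_W[:, None] * self.area[None, :]
        G = self.grad_p2
        Fx = np.einsum("qe,qen,qe->en", T_quad[..., 0, 0], G[..., 0], w) \
            + np.einsum("qe,qen,qe->en", T_quad[..., 0, 1], G[..., 1], w)
        Fy = np.einsum("qe,qen,qe->en", T_quad[..., 1, 0], G[..., 0], w) \
            + np.einsum("qe,qen,qe->en", T_quad[..., 1, 1], G[..., 1], w)
        out = np.zeros(2 * self.n_p2)
        np.add.at(out[:self.n_p2], self.tri6, Fx)
        np.add.at(out[self.n_p2:], self.tri6, Fy)
        return out

    def vector_load_p2(self, f_quad: np.ndarray) -> np.ndarray:
        """int f . v for vector P2 tests; ``f_quad``: (nq, nt, 2).

        Returns (2 * n_p2,) ordered [x-dofs, y-dofs].
        """
        w = QUAD_W[:, None] * self.area[None, :]
        Fx = np.einsum("qe,qn,qe->en", f_quad[..., 0], P2_N, w)
        Fy = np.einsum("qe,qn,qe->en", f_quad[..., 1], P2_N, w)
        out = np.zeros(2 * self.n_p2)
        np.add.at(out[:self.n_p2], self.tri6, Fx)
        np.add.at(out[self.n_p2:], self.tri6, Fy)
        return out

    # -- evaluation helpers -------------------------------------------------

    def quad_points(self) -> np.ndarray:
        """Physical coordinates of the quadrature points, (nq, nt, 2)."""
        verts = self.mesh.points[self.mesh.triangles]  # (nt, 3, 2)
        return np.einsum("qn,enj->qej", QUAD_BARY, verts)

    def p1_at_quad(self, vals: np.ndarray) -> np.ndarray:
        """Vertex field -> values at quadrature points, shape (nq, nt, ...)."""
        v = vals[self.mesh.triangles]  # (nt, 3, ...)
        return np.einsum("qn,en...->qe...", P1_N, v)

    def grad_p2_field(self, u: np.ndarray) -> np.ndarray:
        """P2 vector field (2*n_p2,) -> grad u at quad points (nq, nt, 2, 2).

        Convention: out[..., i, j] = d u_i / d x_j.
        """
        ux = u[:self.n_p2][self.tri6]  # (nt, 6)
        uy = u[self.n_p2:][self.tri6]
        gx = np.einsum("en,qenj->qej", ux, self.grad_p2)
        gy = np.einsum("en,qenj->qej", uy, self.grad_p2)
        return np.stack([gx, gy], axis=2)

    def integrate(self, f_quad: np.ndarray) -> float:
        """Integrate values given at quadrature points over the mesh."""
        return float(np.einsum("qe,q,e->", f_quad, QUAD_W, self.area))


def _scatter(Ke, rows_nodes, cols_nodes, nrows, ncols) -> sp.csr_matrix:
    ne, ni = rows_nodes.shape
    nj = cols_nodes.shape[1]
    rows = np.repeat(rows_nodes, nj, axis=1).ravel()
    cols = np.tile(cols_nodes, (1, ni)).ravel()
    return sp.coo_matrix((Ke.reshape(ne, -1).ravel(), (rows, cols)),
                         shape=(nrows, ncols)).tocsr()


class DirichletPoisson:
    """P1 Laplace solver with Dirichlet data on the whole boundary.

    Factorized once per mesh; reused for the two director components, the
    streamfunction, and the harmonic initialization of the Q-tensor solve.
    """

    def __init__(self, spaces: FemSpaces):
        self.spaces = spaces
        mesh = spaces.mesh
        self.K = spaces.stiffness_p1()
        nb = mesh.boundary_vertices
        free = np.setdiff1d(np.arange(spaces.n_p1), nb)
        self.free = free
        self.fixed = nb
        if free.size == 0:
            raise ValueError("mesh has no interior vertices")
        self._Kff = self.K[np.ix_(free, free)].tocsc()
        self._Kfb = self.K[np.ix_(free, nb)].tocsr()
        self._lu = spla.splu(self._Kff)

    def solve(self, boundary_values: np.ndarray,
              rhs: np.ndarray | None = None) -> np.ndarray:
        """``boundary_values``: per-boundary-vertex data aligned with
        ``mesh.boundary_vertices``; ``rhs``: optional full-length load."""
        x = np.zeros(self.spaces.n_p1)
        x[self.fixed] = boundary_values
        b = -self._Kfb @ boundary_values
        if rhs is not None:
            b = b + rhs[self.free]
        x[self.free] = self._lu.solve(b)
        return x
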