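"""Instantaneous incompressible Stokes flow driven by active stress.

The dimensionless momentum balance is 0 = div sigma with

    sigma = -Pi I + (grad u + grad u^T) - Ca_alpha T,

where T = p p for the polarized director model or T = Q for the Q-tensor
model, and Ca_alpha = alpha R / gamma is the active Capillary number (its
sign encodes extensile > 0 / contractile < 0 activity).  Velocities are in
units of gamma/mu and pressure in units of gamma/R.

Boundary conditions: no-slip u = 0 on the substrate (strongly, including
the contact-point vertices); capillary traction sigma . n = -C n on the
interface (natural boundary term, with the curvature C taken from the
interface polyline).  The traction condition fixes the pressure level, so
the saddle system has no nullspace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import geometry
from ._fem import EDGE_Q, EDGE_W, DirichletPoisson, FemSpaces
from .director import DirectorField
from .qtensor import QField

__all__ = ["FlowState", "StokesOperator", "solve_stokes",
           "streamfunction", "vortex_census"]

#: vortices weaker than this fraction of max |psi| are not counted
VORTEX_AMPLITUDE_FRACTION = 0.05


@dataclass
class FlowState:
    """Velocity (P2) and pressure (P1) at one instant."""

    u: np.ndarray           # (2 * n_p2,), [x-dofs, y-dofs]
    pressure: np.ndarray    # (n_p1,)
    spaces: FemSpaces = field(repr=False, default=None)
    mesh: object = field(repr=False, default=None)

    @property
    def velocity_vertices(self) -> np.ndarray:
        """(n_vertices, 2) velocity sampled at the P1 vertices."""
        n1 = self.spaces.n_p1
        n2 = self.spaces.n_p2
        return np.column_stack([self.u[:n1], self.u[n2:n2 + n1]])

    @property
    def speed(self) -> np.ndarray:
        n2 = self.spaces.n_p2
        return np.hypot(self.u[:n2], self.u[n2:])

    def divergence_residual(self) -> float:
        """Norm of the enforced (weak) incompressibility residual D u.

        This is the constraint the mixed method imposes -- machine-precision
        small for a converged solve.  The pointwise L2 divergence
        (:meth:`divergence_l2`) is only O(h^2) for Taylor-Hood elements.
        """
        D = self.spaces.divergence_matrix()
        return float(np.linalg.norm(D @ self.u))

    def divergence_l2(self) -> float:
        """Pointwise L2 norm of div u over the drop (O(h^2), not zero)."""
        g = self.spaces.grad_p2_field(self.u)
        div = g[..., 0, 0] + g[..., 1, 1]
        return float(np.sqrt(self.spaces.integrate(div ** 2)))


class StokesOperator:
    """Assembled and factorized Taylor-Hood saddle system for one mesh.

    Reused across time steps between remeshes: the matrix depends only on
    the mesh, while the right-hand side (active stress, capillary traction)
    is cheap to rebuild as the interface moves.
    """

    def __init__(self, spaces: FemSpaces):
        self.spaces = spaces
        A = spaces.viscous_matrix()
        D = spaces.divergence_matrix()
        n2, n1 = spaces.n_p2, spaces.n_p1
        M = sp.bmat([[A, -D.T], [D, None]], format="csr")
        sub = spaces.substrate_dofs_p2
        fixed = np.concatenate([sub, n2 + sub])
        self.n_dof = 2 * n2 + n1
        self.free = np.setdiff1d(np.arange(self.n_dof), fixed)
        Mff = M[np.ix_(self.free, self.free)].tocsc()
        self._lu = spla.splu(Mff)

    def solve(self, rhs_velocity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n2, n1 = self.spaces.n_p2, self.spaces.n_p1
        b = np.concatenate([rhs_velocity, np.zeros(n1)])
        x = np.zeros(self.n_dof)
        x[self.free] = self._lu.solve(b[self.free])
        return x[:2 * n2], x[2 * n2:]


def traction_rhs(spaces: FemSpaces, mesh: geometry.DropMesh,
                 curve: geometry.InterfaceCurve) -> np.ndarray:
    """Capillary boundary term -int_interface C (n . v) ds for P2 tests.

    Curvature and normals are evaluated on the *current* interface polyline
    through the (segment, fraction) parameterization stored on the mesh, so
    the capillary restoring force tracks the moving interface even while
    the bulk mesh is being reused.
    """
    t_hat, n_hat, curv = geometry.frame_and_curvature(curve)
    seg = mesh.interface_param[:, 0].astype(int)
    tau = mesh.interface_param[:, 1]
    nxt = np.minimum(seg + 1, curve.n - 1)
    w0 = (1.0 - tau)[:, None]
    pos = w0 * curve.nodes[seg] + (1 - w0) * curve.nodes[nxt]
    nrm = w0 * n_hat[seg] + (1 - w0) * n_hat[nxt]
    nrm /= np.linalg.norm(nrm, axis=1)[:, None]
    C = (1.0 - tau) * curv[seg] + tau * curv[nxt]

    k = mesh.interface_vertices.size
    v0 = np.arange(k - 1)
    v1 = v0 + 1
    mid = np.array([spaces.midpoint_node(int(a), int(b))
                    for a, b in zip(v0, v1)])
    edge_len = np.linalg.norm(pos[v1] - pos[v0], axis=1)

    F = np.zeros(2 * spaces.n_p2)
    n2 = spaces.n_p2
    for xi, wq in zip(EDGE_Q, EDGE_W):
        # 1D P2 shapes on the edge
        N0 = (1 - xi) * (1 - 2 * xi)
        Nm = 4 * xi * (1 - xi)
        N1 = xi * (2 * xi - 1)
        Cq = (1 - xi) * C[v0] + xi * C[v1]
        nq = (1 - xi) * nrm[v0] + xi * nrm[v1]
        nq /= np.linalg.norm(nq, axis=1)[:, None]
        load = -(wq * edge_len * Cq)[:, None] * nq  # (-C n) per unit length
        for N, nodes in ((N0, v0), (N1, v1), (Nm, mid)):
            np.add.at(F[:n2], nodes, N * load[:, 0])
            np.add.at(F[n2:], nodes, N * load[:, 1])
    return F


def active_tensor_quad(spaces: FemSpaces, nematic) -> np.ndarray:
    """Active stress shape T (pp or Q) at quadrature points, (nq, nt, 2, 2)."""
    if isinstance(nematic, DirectorField):
        T_nodes = nematic.tensor_pp()
    elif isinstance(nematic, QField):
        T_nodes = nematic.tensor()
    else:
        raise TypeError(f"unsupported nematic field {type(nematic)!r}")
    return spaces.p1_at_quad(T_nodes)


def solve_stokes(mesh: geometry.DropMesh, curve: geometry.InterfaceCurve,
                 nematic, ca: float,
                 operator: StokesOperator | None = None) -> FlowState:
    """Solve the instantaneous Stokes problem on the current geometry.

    The active stress enters as ``Ca int T : grad v`` on the right-hand
    side; capillary traction as the natural interface term.  ``operator``
    may be passed to reuse the factorized system between steps.
    """
    if not np.isfinite(ca):
        raise ValueError("Ca_alpha must be finite")
    spaces = operator.spaces if operator is not None else FemSpaces(mesh)
    if operator is None:
        operator = StokesOperator(spaces)
    rhs = traction_rhs(spaces, mesh, curve)
    if ca != 0.0:
        rhs = rhs + ca * spaces.active_rhs(active_tensor_quad(spaces, nematic))
    u, p = operator.solve(rhs)
    return FlowState(u=u, pressure=p, spaces=spaces, mesh=mesh)


def streamfunction(state: FlowState, mesh: geometry.DropMesh,
                   poisson: DirichletPoisson | None = None) -> np.ndarray:
    """Streamfunction psi with psi = 0 on the whole boundary.

    Solves laplacian(psi) = -omega with omega the vorticity of u; valid as
    a flow visualization whenever the boundary is (close to) a streamline,
    i.e. at steady state.  Convention u = (d psi / dy, -d psi / dx).
    """
    spaces = state.spaces
    if poisson is None:
        poisson = DirichletPoisson(spaces)
    g = spaces.grad_p2_field(state.u)
    omega = g[..., 1, 0] - g[..., 0, 1]
    rhs = spaces.load_p1(omega)
    return poisson.solve(np.zeros(mesh.boundary_vertices.size), rhs=rhs)


def vorticity_vertices(state: FlowState) -> np.ndarray:
    """Mass-lumped L2 projection of the vorticity onto the vertices."""
    spaces = state.spaces
    g = spaces.grad_p2_field(state.u)
    omega = g[..., 1, 0] - g[..., 0, 1]
    return spaces.load_p1(omega) / spaces.mass_p1_lumped()


def vortex_census(psi: np.ndarray, mesh: geometry.DropMesh,
                  amplitude_fraction: float = VORTEX_AMPLITUDE_FRACTION):
    """Count recirculation cells from interior extrema of psi.

    Returns ``(count, extrema)`` where ``extrema`` is a list of
    ``(location, psi_value)``; the sign of the value gives the rotation
    sense, and adjacent extrema of opposite sign form a counter-rotating
    pair.  Extrema weaker than ``amplitude_fraction * max|psi|`` are
    dropped; extrema closer than ``2 h_mesh`` merge to the strongest.
    """
    psi_max = float(np.abs(psi).max())
    if psi_max == 0.0:
        return 0, []
    tris = mesh.triangles
    nbr_min = np.full(psi.size, np.inf)
    nbr_max = np.full(psi.size, -np.inf)
    for a, b in ((0, 1), (1, 2), (2, 0)):
        for i, j in ((a, b), (b, a)):
            np.minimum.at(nbr_min, tris[:, i], psi[tris[:, j]])
            np.maximum.at(nbr_max, tris[:, i], psi[tris[:, j]])
    interior = np.ones(psi.size, bool)
    interior[mesh.boundary_vertices] = False
    strong = np.abs(psi) >= amplitude_fraction * psi_max
    is_ext = interior & strong & ((psi >= nbr_max) | (psi <= nbr_min))
    cand = np.where(is_ext)[0]
    cand = cand[np.argsort(-np.abs(psi[cand]))]
    kept: list[tuple[np.ndarray, float]] = []
    merge_r = 2.0 * mesh.h_mesh
    for v in cand:
        pt = mesh.points[v]
        if all(np.linalg.norm(pt - loc) > merge_r for loc, _ in kept):
            kept.append((pt.copy(), float(psi[v])))
    return len(kept), kept
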