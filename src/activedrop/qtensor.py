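"""Stationary Landau-de Gennes Q-tensor as the alternative nematic model.

The symmetric traceless tensor Q = S (p p - I/2) respects the head-tail
symmetry that the polarized director description breaks at the boundaries.
Its purely relaxational stationary state solves

    0 = [a - b tr(Q^2)] Q + K_Q laplacian(Q),

componentwise in (Q_xx, Q_xy) with Q_yy = -Q_xx.  The Landau parameters
a, b > 0 set the preferred order S_max = sqrt(2 a / b); the elastic constant
K_Q sets the nematic coherence length xi = sqrt(K_Q / a) (defect core size)
in drop-radius units.  Defaults a=1, b=2 (S_max = 1) and xi = 0.05 make
defect cores resolvable at the default mesh spacing.

Discretization: P1 Galerkin with mass-lumped reaction term; damped Newton
from the harmonic extension of the boundary data, with a semi-implicit
gradient-flow fallback on stagnation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import geometry
from ._fem import DirichletPoisson, FemSpaces
from .director import AnchoringSpec, boundary_director

__all__ = ["QField", "q_from_director", "solve_qtensor", "boundary_q",
           "QSolverError", "LANDAU_A", "LANDAU_B", "K_Q_DEFAULT"]

LANDAU_A = 1.0
LANDAU_B = 2.0
K_Q_DEFAULT = 2.5e-3   # coherence length sqrt(K_Q/a) = 0.05 drop radii


class QSolverError(RuntimeError):
    """Newton and gradient-flow fallback both failed to converge."""


@dataclass
class QField:
    """Per-vertex symmetric traceless tensor, stored as (Q_xx, Q_xy)."""

    qxx: np.ndarray
    qxy: np.ndarray
    a: float = LANDAU_A
    b: float = LANDAU_B
    k_q: float = K_Q_DEFAULT
    mesh: object = None

    @property
    def s_max(self) -> float:
        return float(np.sqrt(2.0 * self.a / self.b))

    @property
    def order(self) -> np.ndarray:
        """Scalar order parameter S = sqrt(2 tr Q^2) per vertex."""
        return 2.0 * np.hypot(self.qxx, self.qxy)

    def tensor(self) -> np.ndarray:
        """(n, 2, 2) dense tensors."""
        Q = np.empty(self.qxx.shape + (2, 2))
        Q[:, 0, 0] = self.qxx
        Q[:, 1, 1] = -self.qxx
        Q[:, 0, 1] = Q[:, 1, 0] = self.qxy
        return Q

    def principal_director(self) -> np.ndarray:
        """Unit eigenvector of the largest eigenvalue (up to sign)."""
        ang = 0.5 * np.arctan2(self.qxy, self.qxx)
        return np.column_stack([np.cos(ang), np.sin(ang)])


def q_from_director(p: np.ndarray, S: float) -> np.ndarray:
    """Q = S (p p - I/2) for a unit director p; invariant under p -> -p."""
    p = np.asarray(p, float)
    if S < 0:
        raise ValueError("S must be non-negative")
    if abs(np.linalg.norm(p) - 1.0) > 1e-9:
        raise ValueError(f"p must be a unit vector, got |p|={np.linalg.norm(p)}")
    return S * (np.outer(p, p) - 0.5 * np.eye(2))


def boundary_q(mesh: geometry.DropMesh, curve: geometry.InterfaceCurve,
               anchoring: AnchoringSpec, s_boundary: float) -> np.ndarray:
    """Strong-anchoring Dirichlet data (nb, 2) = (Q_xx, Q_xy) rows built
    from the boundary director; w and w+2 give identical data."""
    p = boundary_director(mesh, curve, anchoring)
    qxx = s_boundary * (p[:, 0] ** 2 - 0.5)
    qxy = s_boundary * (p[:, 0] * p[:, 1])
    return np.column_stack([qxx, qxy])


def _residual(q, lump, K, kq, a, b):
    """F(q) with q = (n, 2); returns (n, 2).  tr(Q^2) = 2(qxx^2 + qxy^2)."""
    tr2 = 2.0 * np.sum(q ** 2, axis=1)
    return (lump * (a - b * tr2))[:, None] * q - kq * (K @ q)


def solve_qtensor(mesh: geometry.DropMesh, bc: np.ndarray,
                  a: float = LANDAU_A, b: float = LANDAU_B,
                  k_q: float = K_Q_DEFAULT,
                  poisson: DirichletPoisson | None = None,
                  tol: float = 1e-8, max_newton: int = 40) -> QField:
    """Solve the stationary relaxation equation with Dirichlet data ``bc``
    (aligned with ``mesh.boundary_vertices``).

    Newton is initialized from the harmonic extension of the boundary data;
    if it stalls, a semi-implicit gradient flow re-seeds it.  Raises
    :class:`QSolverError` with the residual history if both fail.
    """
    if min(a, b, k_q) <= 0:
        raise ValueError("a, b, K_Q must all be positive")
    if poisson is None:
        poisson = DirichletPoisson(FemSpaces(mesh))
    spaces = poisson.spaces
    K = poisson.K
    lump = spaces.mass_p1_lumped()
    free = poisson.free
    fixed = poisson.fixed
    n = spaces.n_p1

    q = np.column_stack([poisson.solve(bc[:, 0]), poisson.solve(bc[:, 1])])
    q[fixed] = bc

    Kff = K[np.ix_(free, free)].tocsr()
    history: list[float] = []

    def res_free(qfull):
        return _residual(qfull, lump, K, k_q, a, b)[free]

    def newton(qfull, iters):
        for _ in range(iters):
            F = res_free(qfull)
            r = float(np.abs(F).max())
            history.append(r)
            if r <= tol:
                return qfull, True
            J = _jacobian(qfull, lump, Kff, K, free, k_q, a, b)
            delta = spla.splu(J.tocsc()).solve(F.ravel(order="F"))
            step = np.zeros_like(qfull)
            step[free] = delta.reshape((-1, 2), order="F")
            lam, r0 = 1.0, r
            for _ in range(8):
                trial = qfull - lam * step
                if float(np.abs(res_free(trial)).max()) < r0:
                    qfull = trial
                    break
                lam *= 0.5
            else:
                return qfull, False  # stagnation
        return qfull, float(np.abs(res_free(qfull)).max()) <= tol

    q, ok = newton(q, max_newton)
    if not ok:
        # gradient-flow fallback: (M/dt + K_Q L) q+ = M/dt q + M (a - b tr)q
        # diffusion is implicit; dt is capped by the explicit reaction term
        dt = min(0.2 * mesh.h_mesh ** 2 / k_q, 0.2 / a) if k_q else 0.2 / a
        Mdt = sp.diags(lump[free] / dt)
        lu = spla.splu((Mdt + k_q * Kff).tocsc())
        for it in range(4000):
            rhs = (lump[free] / dt)[:, None] * q[free] \
                + (lump[free] * (a - 2 * b * np.sum(q[free] ** 2, axis=1)))[:, None] * q[free] \
                - k_q * (K[free] @ q) + k_q * (Kff @ q[free])
            q[free] = np.column_stack([lu.solve(rhs[:, 0]), lu.solve(rhs[:, 1])])
            if it % 200 == 199 and \
                    float(np.abs(res_free(q)).max()) < 100 * tol:
                break
        q, ok = newton(q, max_newton)
        if not ok:
            raise QSolverError(
                "Q-tensor solve failed; residual history: "
                + ", ".join(f"{r:.3e}" for r in history[-12:]))
    return QField(q[:, 0], q[:, 1], a=a, b=b, k_q=k_q, mesh=mesh)


def _jacobian(q, lump, Kff, K, free, kq, a, b):
    """Jacobian of -F restricted to free vertices, ordered [qxx_f, qxy_f]."""
    qf = q[free]
    tr2 = 2.0 * np.sum(qf ** 2, axis=1)
    lf = lump[free]
    # d/dq of lump*(a - 2b|q|^2*2?)q : careful, tr2 = 2|q|^2
    # F = l (a - b tr2) q - kq K q ;  dF/dq = l[(a - b tr2) I - 4 b q q^T] - kq K
    d00 = lf * ((a - b * tr2) - 4.0 * b * qf[:, 0] ** 2)
    d11 = lf * ((a - b * tr2) - 4.0 * b * qf[:, 1] ** 2)
    d01 = lf * (-4.0 * b * qf[:, 0] * qf[:, 1])
    nf = free.size
    Jr = sp.bmat([[sp.diags(d00) - kq * Kff, sp.diags(d01)],
                  [sp.diags(d01), sp.diags(d11) - kq * Kff]], format="csr")
    return Jr  # Newton step solves Jr * delta = F, update q -= delta
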