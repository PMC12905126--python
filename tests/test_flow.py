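import numpy as np
import pytest

from activedrop import director as dr
from activedrop import flow as fl
from activedrop import geometry as g
from activedrop._fem import (EDGE_Q, EDGE_W, P2_N, QUAD_W, DirichletPoisson,
                             FemSpaces)


def _director(mesh, curve, poisson, w_s, w_i):
    bc = dr.boundary_director(mesh, curve, dr.AnchoringSpec(w_s, w_i))
    return dr.solve_director(mesh, bc, poisson)


@pytest.fixture(scope="module")
def setup(coarse_mesh, coarse_spaces, coarse_poisson):
    return coarse_mesh, coarse_spaces, fl.StokesOperator(coarse_spaces), \
        coarse_poisson


class TestPassiveDrop:
    def test_laplace_equilibrium(self, semicircle, default_mesh):
        """Ca=0 on the exact semicircle: no flow, capillary pressure 1."""
        spaces = FemSpaces(default_mesh)
        poisson = DirichletPoisson(spaces)
        op = fl.StokesOperator(spaces)
        p = _director(default_mesh, semicircle, poisson, 0, 0)
        state = fl.solve_stokes(default_mesh, semicircle, p, 0.0, operator=op)
        assert state.speed.max() <= 1e-3
        # the contact corners carry the usual triple-point pressure
        # artifact; the capillary equilibrium holds away from them
        pts = default_mesh.points
        d = np.minimum(np.hypot(pts[:, 0], pts[:, 1]),
                       np.hypot(pts[:, 0] - 2, pts[:, 1]))
        away = d > g.CORNER_GRADE_RADIUS
        assert np.abs(state.pressure[away] - 1.0).max() < 1e-2
        assert np.sqrt(np.mean((state.pressure - 1.0) ** 2)) < 1e-2

    def test_weak_divergence_residual(self, setup, coarse_curve):
        mesh, spaces, op, poisson = setup
        p = _director(mesh, coarse_curve, poisson, 0, 1)
        state = fl.solve_stokes(mesh, coarse_curve, p, 2.5, operator=op)
        umax = max(state.speed.max(), 1.0)
        assert state.divergence_residual() <= 1e-6 * umax


class TestManufacturedSolution:
    """Method of manufactured solutions on the fixed half-disk.

    u* = (2 y sin(pi x/2), -(pi/2) y^2 cos(pi x/2)) is divergence-free and
    vanishes on the substrate; Pi* = y cos(pi x) + 1.  The corresponding
    body force and interface traction are imposed analytically.
    """

    @staticmethod
    def exact_u(xy):
        x, y = xy[..., 0], xy[..., 1]
        return np.stack([2 * y * np.sin(np.pi * x / 2),
                         -(np.pi / 2) * y ** 2 * np.cos(np.pi * x / 2)],
                        axis=-1)

    @staticmethod
    def exact_p(xy):
        x, y = xy[..., 0], xy[..., 1]
        return y * np.cos(np.pi * x) + 1.0

    @staticmethod
    def grad_u(xy):
        x, y = xy[..., 0], xy[..., 1]
        s, c = np.sin(np.pi * x / 2), np.cos(np.pi * x / 2)
        gxx = np.pi * y * c
        gxy = 2 * s
        gyx = (np.pi ** 2 / 4) * y ** 2 * s
        gyy = -np.pi * y * c
        return np.stack([np.stack([gxx, gxy], -1),
                         np.stack([gyx, gyy], -1)], -2)

    @classmethod
    def body_force(cls, xy):
        # f = grad Pi - laplacian u
        x, y = xy[..., 0], xy[..., 1]
        s, c = np.sin(np.pi * x / 2), np.cos(np.pi * x / 2)
        lap_ux = -(np.pi ** 2 / 2) * y * s
        lap_uy = (np.pi / 2) ** 3 * y ** 2 * c - np.pi * c
        gpx = -np.pi * y * np.sin(np.pi * x)
        gpy = np.cos(np.pi * x)
        return np.stack([gpx - lap_ux, gpy - lap_uy], axis=-1)

    @classmethod
    def stress(cls, xy):
        G = cls.grad_u(xy)
        P = cls.exact_p(xy)
        sym = G + np.swapaxes(G, -1, -2)
        return sym - P[..., None, None] * np.eye(2)

    def _solve(self, h, n):
        curve = g.initial_semicircle(n)
        mesh = g.build_mesh(curve, h, seed=0)
        spaces = FemSpaces(mesh)
        op = fl.StokesOperator(spaces)
        rhs = spaces.vector_load_p2(self.body_force(spaces.quad_points()))
        rhs += self._traction_rhs(spaces, mesh)
        u, p = op.solve(rhs)
        # L2 velocity error via quadrature of the P2 interpolant
        nodes = spaces.nodes_p2
        err = np.column_stack([u[:spaces.n_p2], u[spaces.n_p2:]]) \
            - self.exact_u(nodes)
        ex = np.einsum("en,qn->qe", err[spaces.tri6, 0], P2_N)
        ey = np.einsum("en,qn->qe", err[spaces.tri6, 1], P2_N)
        l2 = np.sqrt(spaces.integrate(ex ** 2 + ey ** 2))
        return l2

    def _traction_rhs(self, spaces, mesh):
        F = np.zeros(2 * spaces.n_p2)
        n2 = spaces.n_p2
        k = mesh.interface_vertices.size
        pts = mesh.points
        for i in range(k - 1):
            v0, v1 = i, i + 1
            mid = spaces.midpoint_node(v0, v1)
            a, b = pts[v0], pts[v1]
            tvec = b - a
            L = np.linalg.norm(tvec)
            nrm = np.array([tvec[1], -tvec[0]]) / L  # outward for CCW order
            nrm = -nrm  # interface ordering left->right: outward is +90 deg
            for xi, wq in zip(EDGE_Q, EDGE_W):
                xq = a + xi * tvec
                trac = self.stress(xq) @ nrm
                N0 = (1 - xi) * (1 - 2 * xi)
                Nm = 4 * xi * (1 - xi)
                N1 = xi * (2 * xi - 1)
                for N, node in ((N0, v0), (N1, v1), (Nm, mid)):
                    F[node] += wq * L * N * trac[0]
                    F[n2 + node] += wq * L * N * trac[1]
        return F

    def test_velocity_converges_second_order(self):
        errs = [self._solve(h, n) for h, n in ((0.1, 33), (0.05, 65))]
        order = np.log2(errs[0] / errs[1])
        assert order >= 2.0


class TestLinearity:
    def test_velocity_affine_in_ca(self, setup, coarse_curve):
        mesh, spaces, op, poisson = setup
        p = _director(mesh, coarse_curve, poisson, 0, 1)
        s0 = fl.solve_stokes(mesh, coarse_curve, p, 0.0, operator=op)
        s1 = fl.solve_stokes(mesh, coarse_curve, p, 1.0, operator=op)
        s2 = fl.solve_stokes(mesh, coarse_curve, p, 2.0, operator=op)
        # active response is exactly linear (Stokes); the capillary part
        # of the solution is Ca-independent
        resid = np.abs((s2.u - s0.u) - 2 * (s1.u - s0.u)).max()
        assert resid < 1e-10
        assert np.abs(s2.u / 2 - s1.u).max() < 5e-3 * np.abs(s1.u).max() + 1e-3


class TestDuality:
    @pytest.mark.parametrize("w_i,ca", [(0, 2.5), (1, 2.5), (2, -2.5)])
    def test_quarter_turn_activity_flip(self, setup, coarse_curve, w_i, ca):
        """(w_s=0, w_i, Ca) and (w_s=1, w_i+1, -Ca) give the same flow: a
        90-degree rotation of the director maps p p to |p|^2 I - p p, and
        the isotropic part is absorbed by the pressure."""
        mesh, spaces, op, poisson = setup
        pa = _director(mesh, coarse_curve, poisson, 0, w_i)
        pb = _director(mesh, coarse_curve, poisson, 1, w_i + 1)
        sa = fl.solve_stokes(mesh, coarse_curve, pa, ca, operator=op)
        sb = fl.solve_stokes(mesh, coarse_curve, pb, -ca, operator=op)
        scale = max(np.abs(sa.u).max(), 1e-9)
        assert np.abs(sa.u - sb.u).max() < 1e-9 * max(scale, 1.0)


class TestMirrorEquivariance:
    def test_mirrored_anchoring_mirrors_flow(self, setup, coarse_curve):
        """On the symmetric shape, w_i=3 flow is the x -> 2-x mirror of the
        w_i=1 flow (u_x negated at mirrored points)."""
        mesh, spaces, op, poisson = setup
        s1 = fl.solve_stokes(mesh, coarse_curve,
                             _director(mesh, coarse_curve, poisson, 0, 1),
                             2.5, operator=op)
        s3 = fl.solve_stokes(mesh, coarse_curve,
                             _director(mesh, coarse_curve, poisson, 0, 3),
                             2.5, operator=op)
        from scipy.interpolate import LinearNDInterpolator
        v1 = s1.velocity_vertices
        interp = LinearNDInterpolator(mesh.points, v1)
        mirrored = mesh.points.copy()
        mirrored[:, 0] = 2.0 - mirrored[:, 0]
        v1m = interp(mirrored)
        ok = ~np.isnan(v1m[:, 0])
        expected = np.column_stack([-v1m[ok, 0], v1m[ok, 1]])
        scale = np.abs(v1).max()
        assert np.abs(s3.velocity_vertices[ok] - expected).max() < 0.05 * scale


class TestStreamfunction:
    def test_zero_flow_zero_psi(self, setup):
        mesh, spaces, op, poisson = setup
        state = fl.FlowState(u=np.zeros(2 * spaces.n_p2),
                             pressure=np.zeros(spaces.n_p1),
                             spaces=spaces, mesh=mesh)
        psi = fl.streamfunction(state, mesh, poisson)
        assert np.abs(psi).max() < 1e-12

    def test_recovers_closed_form(self, setup, coarse_curve):
        """u = curl(psi*) with psi* vanishing on the whole drop boundary;
        the recovered streamfunction must match psi* to O(h^2)."""
        mesh, spaces, op, poisson = setup

        def psi_exact(xy):
            x, y = xy[..., 0], xy[..., 1]
            return (1.0 - (x - 1) ** 2 - y ** 2) * y

        def u_exact(xy):
            x, y = xy[..., 0], xy[..., 1]
            # (d psi/dy, -d psi/dx)
            return np.stack([1.0 - (x - 1) ** 2 - 3 * y ** 2,
                             2 * (x - 1) * y], axis=-1)

        un = u_exact(spaces.nodes_p2)
        u = np.concatenate([un[:, 0], un[:, 1]])
        state = fl.FlowState(u=u, pressure=np.zeros(spaces.n_p1),
                             spaces=spaces, mesh=mesh)
        psi = fl.streamfunction(state, mesh, poisson)
        # psi* is not exactly zero on the polygonal interface; compare in
        # the interior at matching tolerance
        err = np.abs(psi - psi_exact(mesh.points))
        assert err.max() < 10 * mesh.h_mesh ** 2

    def test_curl_of_psi_reconstructs_velocity(self, setup):
        """curl of the recovered psi approximates the generating velocity
        in L2 (the boundary is a streamline for this constructed state)."""
        mesh, spaces, op, poisson = setup

        def u_exact(xy):
            x, y = xy[..., 0], xy[..., 1]
            return np.stack([1.0 - (x - 1) ** 2 - 3 * y ** 2,
                             2 * (x - 1) * y], axis=-1)

        un = u_exact(spaces.nodes_p2)
        u = np.concatenate([un[:, 0], un[:, 1]])
        state = fl.FlowState(u=u, pressure=np.zeros(spaces.n_p1),
                             spaces=spaces, mesh=mesh)
        psi = fl.streamfunction(state, mesh, poisson)
        gpsi = np.einsum("en,enj->ej", psi[mesh.triangles], spaces.grad_p1)
        u_from_psi = np.stack([gpsi[:, 1], -gpsi[:, 0]], -1)  # per element
        cent = mesh.points[mesh.triangles].mean(axis=1)
        diff = np.linalg.norm(u_from_psi - u_exact(cent), axis=1)
        l2 = np.sqrt(np.sum(diff ** 2 * spaces.area) / np.sum(spaces.area))
        scale = np.abs(un).max()
        assert l2 < 0.15 * scale  # P1 gradients: first-order reconstruction


class TestVortexCensus:
    def test_quiescent(self, setup):
        mesh = setup[0]
        n, ext = fl.vortex_census(np.zeros(mesh.n_points), mesh)
        assert n == 0 and ext == []

    def test_two_known_cells(self, setup):
        mesh = setup[0]
        pts = mesh.points
        c1, c2 = np.array([0.6, 0.45]), np.array([1.4, 0.45])
        psi = np.exp(-np.sum((pts - c1) ** 2, 1) / 0.02) \
            - np.exp(-np.sum((pts - c2) ** 2, 1) / 0.02)
        n, ext = fl.vortex_census(psi, mesh)
        assert n == 2
        signs = sorted(np.sign(v) for _, v in ext)
        assert signs == [-1.0, 1.0]
        locs = sorted([e[0][0] for e in ext])
        assert abs(locs[0] - 0.6) < 2 * mesh.h_mesh
        assert abs(locs[1] - 1.4) < 2 * mesh.h_mesh

    def test_weak_cells_thresholded(self, setup):
        mesh = setup[0]
        pts = mesh.points
        psi = np.exp(-np.sum((pts - [1.0, 0.5]) ** 2, 1) / 0.02) \
            + 0.01 * np.exp(-np.sum((pts - [0.4, 0.3]) ** 2, 1) / 0.01)
        n, _ = fl.vortex_census(psi, mesh)
        assert n == 1


class TestEntropyPositivity:
    @pytest.mark.parametrize("w_i,ca", [(0, 2.5), (1, -2.5), (2, 5.0)])
    def test_viscous_rate_nonnegative(self, setup, coarse_curve, w_i, ca):
        from activedrop.diagnostics import entropy_rates
        mesh, spaces, op, poisson = setup
        p = _director(mesh, coarse_curve, poisson, 0, w_i)
        state = fl.solve_stokes(mesh, coarse_curve, p, ca, operator=op)
        rates = entropy_rates(state, p, ca)
        assert rates.s_dot_v >= 0.0
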