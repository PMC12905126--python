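"""Drop geometry: interface polyline, curvature, triangulation, shape metrics.

The only dynamical state of the model is the liquid-air interface, an ordered
polyline pinned at the two contact points (0, 0) and (2, 0) (lengths in units
of the initial drop radius R).  Everything else -- the triangulated bulk, the
nematic field, the Stokes flow -- is recomputed quasi-statically from it.

Conventions fixed here and used by every downstream module:

* the interface is ordered by increasing arclength from the left contact,
  over the apex, to the right contact;
* ``t_hat`` is the unit tangent along increasing arclength and
  ``n_hat = R(+pi/2) t_hat`` is the outward normal;
* the interfacial curvature ``C`` (twice the mean curvature, i.e. div n_hat)
  is +1 on the unit semicircle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "InterfaceCurve",
    "DropMesh",
    "initial_semicircle",
    "frame_and_curvature",
    "enclosed_area",
    "redistribute",
    "mirror_asymmetry",
    "mirror_curve",
    "build_mesh",
    "drop_polygon",
]

CONTACT_LEFT = np.array([0.0, 0.0])
CONTACT_RIGHT = np.array([2.0, 0.0])

#: radius around each contact point inside which the mesh is graded finer
CORNER_GRADE_RADIUS = 0.2
#: edge-length reduction factor reached at the contact points
CORNER_GRADE_FACTOR = 0.25


class GeometryError(ValueError):
    """Invalid or degenerate drop geometry."""


# ---------------------------------------------------------------------------
# Interface curve
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InterfaceCurve:
    """Ordered polyline of the liquid-air interface with pinned endpoints.

    Parameters
    ----------
    nodes
        ``(n, 2)`` array of points ordered left contact -> apex -> right
        contact.  The first node must be ``(0, 0)`` and the last ``(2, 0)``;
        all interior nodes must have ``y > 0`` and the polyline must be
        simple (no self-intersection).
    """

    nodes: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        if nodes.ndim != 2 or nodes.shape[1] != 2 or nodes.shape[0] < 3:
            raise GeometryError("interface needs an (n>=3, 2) node array")
        object.__setattr__(self, "nodes", nodes)
        if not (np.allclose(nodes[0], CONTACT_LEFT, atol=1e-12)
                and np.allclose(nodes[-1], CONTACT_RIGHT, atol=1e-12)):
            raise GeometryError(
                "contact points must be pinned at (0,0) and (2,0); got "
                f"{nodes[0]} and {nodes[-1]}")
        if np.any(nodes[1:-1, 1] <= 0.0):
            k = int(np.argmin(nodes[1:-1, 1])) + 1
            raise GeometryError(
                f"interior node {k} at {nodes[k]} is not above the substrate")
        seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
        if np.any(seg < 1e-14):
            raise GeometryError("duplicate consecutive interface nodes")
        if not LineString(nodes).is_simple:
            i, j = _find_self_intersection(nodes)
            raise GeometryError(
                f"interface self-intersects: segment {i} crosses segment {j}")

    @property
    def n(self) -> int:
        return self.nodes.shape[0]

    @property
    def arclength(self) -> np.ndarray:
        """Cumulative arclength coordinate of each node, starting at 0."""
        seg = np.linalg.norm(np.diff(self.nodes, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def to_csv(self, path) -> None:
        """Write (s, x, y, C) columns as CSV."""
        _, _, curv = frame_and_curvature(self)
        data = np.column_stack([self.arclength, self.nodes, curv])
        header = "s,x,y,C"
        np.savetxt(path, data, delimiter=",", header=header, comments="",
                   fmt="%.12g")

    @classmethod
    def from_csv(cls, path) -> "InterfaceCurve":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(data[:, 1:3])


def _find_self_intersection(nodes: np.ndarray) -> tuple[int, int]:
    """Brute-force search for the first pair of crossing segments."""
    n = nodes.shape[0] - 1
    for i in range(n):
        a, b = nodes[i], nodes[i + 1]
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                pass  # non-adjacent even though they share no node
            c, d = nodes[j], nodes[j + 1]
            if _segments_cross(a, b, c, d):
                return i, j
    return -1, -1


def _segments_cross(a, b, c, d) -> bool:
    def orient(p, q, r):
        return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])

    o1, o2 = orient(a, b, c), orient(a, b, d)
    o3, o4 = orient(c, d, a), orient(c, d, b)
    return (o1 * o2 < 0) and (o3 * o4 < 0)


def initial_semicircle(n_boundary: int) -> InterfaceCurve:
    """Semicircular rest shape of radius 1 centred at (1, 0).

    Nodes are equally spaced in arc angle with endpoints exactly at the
    contact points.  ``n_boundary`` must be at least 16 so that the capillary
    traction of the initial condition is resolved.
    """
    if n_boundary < 16:
        raise GeometryError(
            f"n_boundary={n_boundary} is too coarse; need at least 16 nodes "
            "to resolve the initial semicircle")
    theta = np.linspace(np.pi, 0.0, n_boundary)
    nodes = np.column_stack([1.0 + np.cos(theta), np.sin(theta)])
    nodes[0] = CONTACT_LEFT
    nodes[-1] = CONTACT_RIGHT
    return InterfaceCurve(nodes)


# ---------------------------------------------------------------------------
# Frames and curvature
# ---------------------------------------------------------------------------


def frame_and_curvature(curve) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-node tangent, outward normal and curvature of a polyline.

    Accepts an :class:`InterfaceCurve` or a raw ``(n, 2)`` array.  The
    tangent is the normalized central difference of neighbouring nodes
    (one-sided at the endpoints); the normal is the tangent rotated by +90
    degrees, which points out of the fluid for the standard node ordering.
    Curvature uses the circle through each node and its two neighbours
    (one-sided triples at the endpoints), signed so that the unit semicircle
    has ``C = +1``; collinear triples give exactly 0.
    """
    nodes = curve.nodes if isinstance(curve, InterfaceCurve) else np.asarray(curve, float)
    n = nodes.shape[0]
    if n < 3:
        raise GeometryError("need at least 3 nodes for frames")
    seg = np.diff(nodes, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    if np.any(seglen < 1e-14):
        raise GeometryError("duplicate consecutive nodes")

    chord = np.empty_like(nodes)
    chord[1:-1] = nodes[2:] - nodes[:-2]
    chord[0] = seg[0]
    chord[-1] = seg[-1]
    t_hat = chord / np.linalg.norm(chord, axis=1)[:, None]
    n_hat = np.column_stack([-t_hat[:, 1], t_hat[:, 0]])

    # three-point circumscribed circle; one-sided at the ends
    ia = np.concatenate([[0], np.arange(0, n - 2), [n - 3]])
    ib = np.concatenate([[1], np.arange(1, n - 1), [n - 2]])
    ic = np.concatenate([[2], np.arange(2, n), [n - 1]])
    a, b, c = nodes[ia], nodes[ib], nodes[ic]
    ab, bc, ca = b - a, c - b, a - c
    cross = ab[:, 0] * (-ca[:, 1]) - ab[:, 1] * (-ca[:, 0])  # cross(ab, ac)
    denom = (np.linalg.norm(ab, axis=1) * np.linalg.norm(bc, axis=1)
             * np.linalg.norm(ca, axis=1))
    curv = np.where(np.abs(cross) < 1e-14 * np.maximum(denom, 1e-300),
                    0.0, -2.0 * cross / np.maximum(denom, 1e-300))
    return t_hat, n_hat, curv


def enclosed_area(curve) -> float:
    """Polygon area of the drop (interface closed along the substrate)."""
    nodes = curve.nodes if isinstance(curve, InterfaceCurve) else np.asarray(curve, float)
    x, y = nodes[:, 0], nodes[:, 1]
    # shoelace including the closing edge last -> first (along y=0)
    area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return float(abs(area))


def redistribute(curve: InterfaceCurve, n: int | None = None) -> InterfaceCurve:
    """Re-place nodes at equal arclength along the current polyline.

    The interpolant is the piecewise-linear curve itself, so new nodes lie
    exactly on the input shape; endpoints are unchanged.  Tangential motion
    of the interface is a pure reparameterization, which this absorbs.  A
    uniform normal nudge of the interior nodes (second order in the
    spacing) restores the enclosed polygon area exactly, since area is the
    conserved quantity of the incompressible dynamics.
    """
    s = curve.arclength
    n = curve.n if n is None else int(n)
    s_new = np.linspace(0.0, s[-1], n)
    nodes = np.column_stack([np.interp(s_new, s, curve.nodes[:, 0]),
                             np.interp(s_new, s, curve.nodes[:, 1])])
    nodes[0] = CONTACT_LEFT
    nodes[-1] = CONTACT_RIGHT
    target = enclosed_area(curve)
    _, n_hat, _ = frame_and_curvature(nodes)
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    w = np.zeros(n)
    w[:-1] += 0.5 * seg
    w[1:] += 0.5 * seg
    w[0] = w[-1] = 0.0
    delta = (target - enclosed_area(nodes)) / w.sum()
    nodes[w > 0] += delta * n_hat[w > 0]
    # the nudge must not push wall-hugging nodes through the substrate
    y_floor = 0.5 * float(curve.nodes[1:-1, 1].min())
    nodes[1:-1, 1] = np.maximum(nodes[1:-1, 1], min(y_floor, 1e-4))
    return InterfaceCurve(nodes)


def drop_polygon(curve) -> Polygon:
    """Shapely polygon of the drop region (interface + substrate closure)."""
    nodes = curve.nodes if isinstance(curve, InterfaceCurve) else np.asarray(curve, float)
    return Polygon(nodes)  # closing edge (2,0)->(0,0) runs along y=0


def mirror_curve(curve: InterfaceCurve) -> InterfaceCurve:
    """Reflect the drop about the midline x = 1 (reversing the ordering)."""
    nodes = curve.nodes[::-1].copy()
    nodes[:, 0] = 2.0 - nodes[:, 0]
    return InterfaceCurve(nodes)


def mirror_asymmetry(curve: InterfaceCurve) -> float:
    """Area of the symmetric difference with the x -> 2-x reflection, over
    the drop area.  0 for mirror-symmetric drops, up to 1."""
    poly = drop_polygon(curve)
    refl = drop_polygon(mirror_curve(curve))
    diff = poly.symmetric_difference(refl)
    return float(diff.area / poly.area)


# ---------------------------------------------------------------------------
# Meshing
# ---------------------------------------------------------------------------

SUBSTRATE, INTERFACE = 0, 1


@dataclass
class DropMesh:
    """Conforming triangulation of the drop with tagged boundary edges."""

    points: np.ndarray          # (np, 2) vertex coordinates
    triangles: np.ndarray       # (nt, 3) CCW connectivity
    boundary_edges: np.ndarray  # (ne, 2) vertex index pairs
    boundary_tags: np.ndarray   # (ne,) SUBSTRATE or INTERFACE
    h_mesh: float
    #: mesh vertex index of each interface-curve node, in curve order
    curve_vertices: np.ndarray = field(default=None)
    #: for every interface boundary vertex: index + arclength fraction into
    #: the generating curve (used to re-evaluate frames on a moved curve)
    interface_vertices: np.ndarray = field(default=None)   # vertex ids, ordered
    interface_param: np.ndarray = field(default=None)      # (k, 2): (seg, tau)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def substrate_vertices(self) -> np.ndarray:
        e = self.boundary_edges[self.boundary_tags == SUBSTRATE]
        return np.unique(e)

    @property
    def boundary_vertices(self) -> np.ndarray:
        return np.unique(self.boundary_edges)

    def triangle_quality(self) -> float:
        """Minimum interior angle over all triangles, in degrees."""
        return float(np.min(_triangle_angles(self.points, self.triangles)))

    def area(self) -> float:
        p = self.points
        t = self.triangles
        d1 = p[t[:, 1]] - p[t[:, 0]]
        d2 = p[t[:, 2]] - p[t[:, 0]]
        return float(0.5 * np.sum(np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])))


def _triangle_angles(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = points[tris]
    angles = np.empty(tris.shape)
    for k in range(3):
        u = p[:, (k + 1) % 3] - p[:, k]
        v = p[:, (k + 2) % 3] - p[:, k]
        cosang = np.sum(u * v, axis=1) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
        angles[:, k] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return angles.min(axis=1)


def _size_function(pts: np.ndarray, h_mesh: float) -> np.ndarray:
    """Target edge length: graded from 0.25*h at the contact points up to h
    beyond distance 0.2, resolving the corner stress singularity and the
    anchoring-mismatch defects there."""
    d = np.minimum(np.linalg.norm(pts - CONTACT_LEFT, axis=-1),
                   np.linalg.norm(pts - CONTACT_RIGHT, axis=-1))
    frac = np.clip(d / CORNER_GRADE_RADIUS, 0.0, 1.0)
    return h_mesh * (CORNER_GRADE_FACTOR + (1.0 - CORNER_GRADE_FACTOR) * frac)


def _interface_boundary_nodes(curve: InterfaceCurve, hfun):
    """Subdivide curve segments to satisfy the graded size target.

    Returns the boundary node coordinates (curve nodes plus subdivision
    points, in order), the (segment, fraction) parameterization of each, and
    the positions of the original curve nodes within that list.  Subdivision
    keeps every original curve node as a mesh vertex, so the flow solution
    can be read off directly at the kinematic nodes.
    """
    nodes = curve.nodes
    pts, param, curve_pos = [], [], []
    for k in range(curve.n - 1):
        a, b = nodes[k], nodes[k + 1]
        curve_pos.append(len(pts))
        pts.append(a)
        param.append((k, 0.0))
        seglen = np.linalg.norm(b - a)
        target = float(hfun((0.5 * (a + b))[None, :])[0])
        nsub = int(np.ceil(seglen / max(target, 1e-9) - 1e-9))
        for j in range(1, nsub):
            tau = j / nsub
            pts.append(a + tau * (b - a))
            param.append((k, tau))
    curve_pos.append(len(pts))
    pts.append(nodes[-1])
    param.append((curve.n - 2, 1.0))
    return (np.asarray(pts), np.asarray(param, dtype=float),
            np.asarray(curve_pos, dtype=int))


def _substrate_nodes(hfun) -> np.ndarray:
    """Graded 1D point set on the substrate segment [0, 2] (excluding ends)."""
    xf = np.linspace(0.0, 2.0, 2001)
    dens = 1.0 / hfun(np.column_stack([xf, np.zeros_like(xf)]))
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1])
                                           * np.diff(xf))])
    n = int(round(cum[-1]))
    q = np.linspace(0.0, cum[-1], n + 1)
    x = np.interp(q, cum, xf)
    return x[1:-1]


def build_mesh(curve: InterfaceCurve, h_mesh: float, seed: int = 0,
               warm_start: np.ndarray | None = None,
               size_cap: float | None = None) -> DropMesh:
    """Triangulate the drop with a force-equilibrium (distmesh-style) mesher.

    Edge lengths follow the graded size field of :func:`_size_function`
    (optionally capped at ``size_cap`` for thin-film runs).  Interior seeds
    come from a deterministic RNG (``seed``) or, for warm starts during time
    stepping, from the interior vertices of the previous mesh.  Raises
    :class:`GeometryError` for self-intersecting input (naming the offending
    segment pair, via the curve validator) or irrecoverably bad quality.
    """
    if h_mesh > 0.2:
        raise GeometryError(f"h_mesh={h_mesh} too coarse; need h_mesh <= 0.2")
    # curve construction already rejects self-intersections with the pair named
    poly = drop_polygon(curve)

    def hfun(p):
        h = _size_function(np.asarray(p, float), h_mesh)
        return np.minimum(h, size_cap) if size_cap else h

    int_pts, int_param, curve_pos = _interface_boundary_nodes(curve, hfun)
    sub_x = _substrate_nodes(hfun)
    sub_pts = np.column_stack([sub_x, np.zeros_like(sub_x)])
    fixed = np.vstack([int_pts, sub_pts])
    n_interface = int_pts.shape[0]

    rng = np.random.default_rng(seed)
    if warm_start is not None and len(warm_start):
        interior = _filter_interior(warm_start, poly, fixed, hfun)
        n_iter = 5
    else:
        interior = _seed_interior(poly, fixed, hfun, rng)
        n_iter = 40

    interior = _smooth(interior, fixed, poly, hfun, n_iter)

    # quality loop: extra smoothing / cleanup until min angle is acceptable
    minang = 0.0
    for attempt in range(6):
        interior = _filter_interior(interior, poly, fixed, hfun)
        pts, tris, ok = _triangulate(fixed, interior, poly)
        if ok:
            ok = _boundary_conforming(tris, n_interface)
        if ok:
            minang = np.min(_triangle_angles(pts, tris))
            if minang >= 15.0:
                break
            bad_ids = np.unique(tris[_triangle_angles(pts, tris) < 15.0])
            movable = bad_ids[bad_ids >= fixed.shape[0]] - fixed.shape[0]
        else:
            movable = np.empty(0, int)
        if attempt == 3:
            # cold restart with a reseeded point set
            rng = np.random.default_rng(seed + 1000 + attempt)
            interior = _seed_interior(poly, fixed, hfun, rng)
            interior = _smooth(interior, fixed, poly, hfun, 40)
        elif movable.size:
            # bad interior points hugging the boundary get dropped
            keep = np.ones(interior.shape[0], bool)
            d_edge = shapely.distance(shapely.points(interior[movable]),
                                      poly.exterior)
            keep[movable[d_edge < 0.7 * hfun(interior[movable])]] = False
            interior = _smooth(interior[keep], fixed, poly, hfun, 8)
        else:
            interior = _smooth(interior, fixed, poly, hfun, 12)
    else:
        raise GeometryError(
            f"mesh quality unrecoverable: min angle {minang:.2f} deg < 15")

    mesh = _finalize(pts, tris, h_mesh)
    mesh.curve_vertices = curve_pos
    mesh.interface_vertices = np.arange(n_interface)
    mesh.interface_param = int_param
    return mesh


def _contains(poly: Polygon, pts: np.ndarray, margin: float = 0.0) -> np.ndarray:
    if margin:
        poly = poly.buffer(-margin)
    return shapely.contains_xy(poly, pts[:, 0], pts[:, 1])


def _seed_interior(poly, fixed, hfun, rng) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    h0 = float(np.min(hfun(fixed))) * 0.9
    xs = np.arange(minx + h0, maxx, h0)
    ys = np.arange(miny + h0 * 0.866, maxy, h0 * 0.866)
    X, Y = np.meshgrid(xs, ys)
    X[1::2] += h0 / 2  # hex offset
    cand = np.column_stack([X.ravel(), Y.ravel()])
    h = hfun(cand)
    keep = rng.random(cand.shape[0]) < (h0 / h) ** 2
    cand = cand[keep]
    cand = cand[_contains(poly, cand)]
    return _filter_interior(cand, poly, fixed, hfun)


def _filter_interior(pts, poly, fixed, hfun) -> np.ndarray:
    """Keep candidate interior points: inside, clear of the boundary
    polyline, and not mutually (near-)duplicate."""
    if not len(pts):
        return np.empty((0, 2))
    pts = pts[_contains(poly, pts)]
    if not len(pts):
        return np.empty((0, 2))
    d_edge = shapely.distance(shapely.points(pts), poly.exterior)
    pts = pts[d_edge > 0.55 * hfun(pts)]
    if len(pts) > 1:
        pairs = cKDTree(pts).query_pairs(1e-3, output_type="ndarray")
        if len(pairs):
            drop = np.zeros(len(pts), bool)
            drop[pairs[:, 1]] = True
            pts = pts[~drop]
    return pts


def _smooth(interior, fixed, poly, hfun, n_iter) -> np.ndarray:
    """Distmesh force equilibrium: repulsive-only springs on Delaunay edges."""
    if not len(interior):
        return interior
    nfix = fixed.shape[0]
    for _ in range(n_iter):
        pts = np.vstack([fixed, interior])
        tri = Delaunay(pts)
        cent = pts[tri.simplices].mean(axis=1)
        good = tri.simplices[_contains(poly, cent)]
        edges = np.unique(np.sort(np.concatenate(
            [good[:, [0, 1]], good[:, [1, 2]], good[:, [0, 2]]]), axis=1), axis=0)
        vec = pts[edges[:, 1]] - pts[edges[:, 0]]
        L = np.linalg.norm(vec, axis=1)
        hmid = hfun(0.5 * (pts[edges[:, 0]] + pts[edges[:, 1]]))
        L0 = hmid * 1.2 * np.sqrt(np.sum(L ** 2) / np.sum(hmid ** 2))
        F = np.maximum(L0 - L, 0.0) / np.maximum(L, 1e-12)
        Fvec = F[:, None] * vec
        force = np.zeros_like(pts)
        np.subtract.at(force, edges[:, 0], Fvec)
        np.add.at(force, edges[:, 1], Fvec)
        interior = interior + 0.2 * force[nfix:]
        # pull escaped points back inside
        out = ~_contains(poly, interior)
        if out.any():
            interior[out] = _project_inside(interior[out], poly, hfun)
    return interior


def _project_inside(pts, poly, hfun) -> np.ndarray:
    bdry = poly.exterior
    out = []
    for p in pts:
        q = bdry.interpolate(bdry.project(Point(p)))
        q = np.array([q.x, q.y])
        inward = np.array(poly.representative_point().coords[0]) - q
        nrm = np.linalg.norm(inward)
        if nrm > 1e-12:
            q = q + inward / nrm * 0.3 * float(hfun(q[None, :])[0])
        out.append(q)
    res = np.asarray(out)
    inside = _contains(poly, res)
    # as a last resort collapse to the representative interior point
    if not inside.all():
        rp = np.array(poly.representative_point().coords[0])
        res[~inside] = rp
    return res


def _triangulate(fixed, interior, poly):
    """Delaunay + inside filter.  Fails (ok=False) if any fixed boundary
    vertex ends up unreferenced, i.e. the boundary was not recovered."""
    pts = np.vstack([fixed, interior]) if len(interior) else fixed.copy()
    tri = Delaunay(pts)
    cent = pts[tri.simplices].mean(axis=1)
    keep = tri.simplices[_contains(poly, cent)]
    # drop zero-area slivers (collinear boundary subdivision points whose
    # centroid lands numerically "inside"); real triangles survive
    d1 = pts[keep[:, 1]] - pts[keep[:, 0]]
    d2 = pts[keep[:, 2]] - pts[keep[:, 0]]
    area2 = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    keep = keep[np.abs(area2) > 1e-9]
    # enforce CCW orientation
    d1 = pts[keep[:, 1]] - pts[keep[:, 0]]
    d2 = pts[keep[:, 2]] - pts[keep[:, 0]]
    flip = (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]) < 0
    keep[flip] = keep[flip][:, [0, 2, 1]]
    used = np.unique(keep)
    nfix = fixed.shape[0]
    if used.size and (used[:nfix] != np.arange(min(nfix, used.size))).any():
        return pts, keep, False  # a boundary vertex was lost
    # drop unreferenced interior vertices (escaped duplicates etc.)
    if used.size != pts.shape[0]:
        remap = -np.ones(pts.shape[0], int)
        remap[used] = np.arange(used.size)
        keep = remap[keep]
        pts = pts[used]
    return pts, keep, True


def _boundary_conforming(tris, n_interface) -> bool:
    """Every consecutive interface node pair must appear as a mesh edge."""
    edges = np.sort(np.concatenate(
        [tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [0, 2]]]), axis=1)
    have = set(map(tuple, np.unique(edges, axis=0)))
    return all((i, i + 1) in have for i in range(n_interface - 1))


def _finalize(pts, tris, h_mesh) -> DropMesh:
    edges = np.sort(np.concatenate(
        [tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [0, 2]]]), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    bedges = uniq[counts == 1]
    on_sub = np.all(np.abs(pts[bedges][:, :, 1]) < 1e-12, axis=1)
    tags = np.where(on_sub, SUBSTRATE, INTERFACE)
    return DropMesh(points=pts, triangles=tris, boundary_edges=bedges,
                    boundary_tags=tags, h_mesh=h_mesh)
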