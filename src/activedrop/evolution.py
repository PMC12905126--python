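"""Time marching of the interface via the kinematic condition.

Each step is quasi-static: the mesh, nematic field and Stokes flow are
instantaneous functionals of the interface shape, which is the only
dynamical state.  Interface nodes move with the normal fluid velocity
(tangential motion is a pure reparameterization, absorbed by arclength
redistribution); the contact points stay pinned.  Explicit first-order
integration with a capillary-limited time step keeps each step cheap.

Between remeshes (triggered by accumulated boundary displacement or mesh
quality) the assembled, factorized Stokes operator and the nematic field
are reused; the capillary traction is re-evaluated from the moving
interface polyline every step, which preserves the stabilizing capillary
feedback at negligible cost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import geometry
from ._fem import DirichletPoisson, FemSpaces
from .director import (DEFECT_THRESHOLD, AnchoringSpec, DirectorField,
                       boundary_director, defect_census, solve_director)
from .diagnostics import (MorphologyThresholds, classify_morphology,
                          entropy_rates, max_speed)
from .flow import (StokesOperator, solve_stokes, streamfunction,
                   vortex_census)
from .qtensor import (K_Q_DEFAULT, LANDAU_A, LANDAU_B, boundary_q,
                      solve_qtensor)

__all__ = ["SimConfig", "AnchoringSchedule", "DiagnosticsRecord",
           "SimResult", "Simulation", "step", "run", "steady_state_time",
           "apply_schedule_switch", "SimulationError"]

TARGET_AREA = np.pi / 2.0


class SimulationError(RuntimeError):
    """Aborted run; carries the offending interface for post-mortem."""

    def __init__(self, message, curve_nodes=None, t=None):
        super().__init__(message)
        self.curve_nodes = curve_nodes
        self.t = t


@dataclass(frozen=True)
class AnchoringSchedule:
    """Piecewise-constant interfacial winding number; fixed substrate w_s."""

    w_s: int
    entries: tuple  # ((t_0=0, w_i), (t_1, w_i), ...) strictly increasing

    def __post_init__(self):
        entries = tuple((float(t), int(w) % 4) for t, w in self.entries)
        if not entries or entries[0][0] != 0.0:
            raise ValueError("schedule must start with an entry at t = 0")
        times = [t for t, _ in entries]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("switch times must be strictly increasing")
        object.__setattr__(self, "entries", entries)

    def w_i_at(self, t: float) -> int:
        w = self.entries[0][1]
        for tk, wk in self.entries:
            if t >= tk - 1e-12:
                w = wk
        return w

    def next_switch_after(self, t: float):
        for tk, _ in self.entries:
            if tk > t + 1e-12:
                return tk
        return None

    @property
    def last_switch_time(self) -> float:
        return self.entries[-1][0]


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one run; every numeric output is a
    deterministic function of this object."""

    ca: float = 0.0
    w_s: int = 0
    w_i: int = 0
    schedule: AnchoringSchedule | None = None
    nematic_model: str = "director"          # "director" | "qtensor"
    h_mesh: float = 0.05
    dt_max: float | None = None              # default 0.4 * h_mesh
    cfl_factor: float = 0.5
    t_end: float = 50.0
    steady_tol: float = 1e-3
    steady_window: float = 1.0
    landau_a: float = LANDAU_A
    landau_b: float = LANDAU_B
    k_q: float = K_Q_DEFAULT
    mesh_seed: int = 0
    output_dt: float = 0.25
    normalize_director: bool = False
    conserve_area: bool = True
    allow_thin_film: bool = True
    stop_when_steady: bool = True
    remesh_displacement: float = 0.2         # fraction of h_mesh
    wall_clearance_factor: float = 0.05      # interface floor, x h_mesh
    n_boundary: int | None = None            # default: spacing ~ h_mesh
    defect_threshold: float = DEFECT_THRESHOLD
    morphology: MorphologyThresholds = field(default_factory=MorphologyThresholds)

    def __post_init__(self):
        if self.dt_max is not None and self.dt_max <= 0:
            raise ValueError("dt_max must be positive")
        if not 0.0 < self.cfl_factor <= 1.0:
            raise ValueError("cfl_factor must be in (0, 1]")
        if self.steady_tol <= 0:
            raise ValueError("steady_tol must be positive")
        if self.nematic_model not in ("director", "qtensor"):
            raise ValueError(f"unknown nematic model {self.nematic_model!r}")

    @property
    def resolved_dt_max(self) -> float:
        # explicit capillary forcing is stable for dt of order the node
        # spacing (in viscocapillary units); 0.4 h keeps a safety margin
        return self.dt_max if self.dt_max is not None else 0.4 * self.h_mesh

    @property
    def resolved_n_boundary(self) -> int:
        if self.n_boundary is not None:
            return self.n_boundary
        return max(17, int(np.ceil(np.pi / self.h_mesh)) + 1)

    def anchoring_at(self, t: float) -> AnchoringSpec:
        if self.schedule is not None:
            return AnchoringSpec(self.schedule.w_s, self.schedule.w_i_at(t))
        return AnchoringSpec(self.w_s, self.w_i)


@dataclass
class DiagnosticsRecord:
    t: float
    max_speed: float
    area: float
    asymmetry: float
    s_dot_v: float
    s_dot_a: float
    s_dot_tot: float
    n_vortices: int
    n_defects: int
    w_i: int
    max_normal_speed: float

    FIELDS = ("t", "max_speed", "area", "asymmetry", "s_dot_v", "s_dot_a",
              "s_dot_tot", "n_vortices", "n_defects", "w_i",
              "max_normal_speed")


class _StepContext:
    """Caches mesh, factorized operators and the nematic field between
    remeshes; the interface curve remains the only true state."""

    def __init__(self, config: SimConfig):
        self.config = config
        self.mesh = None
        self.spaces = None
        self.poisson = None
        self.stokes = None
        self.nematic = None
        self.anchoring = None
        self.cum_displacement = np.inf  # force initial build
        self.size_cap = None
        self.n_remesh = 0
        self.last_normal_speed = 0.0

    def invalidate(self):
        self.cum_displacement = np.inf

    def ensure(self, curve: geometry.InterfaceCurve, anchoring: AnchoringSpec):
        cfg = self.config
        stale = (self.mesh is None
                 or self.cum_displacement
                 > cfg.remesh_displacement * cfg.h_mesh
                 or anchoring != self.anchoring)
        if not stale:
            return
        warm = None
        if self.mesh is not None:
            interior = np.setdiff1d(np.arange(self.mesh.n_points),
                                    self.mesh.boundary_vertices)
            warm = self.mesh.points[interior]
        self.mesh = geometry.build_mesh(
            curve, cfg.h_mesh, seed=cfg.mesh_seed, warm_start=warm,
            size_cap=self.size_cap)
        self.spaces = FemSpaces(self.mesh)
        self.poisson = DirichletPoisson(self.spaces)
        self.stokes = StokesOperator(self.spaces)
        self._solve_nematic(curve, anchoring)
        self.anchoring = anchoring
        self.cum_displacement = 0.0
        self.n_remesh += 1

    def _solve_nematic(self, curve, anchoring):
        cfg = self.config
        if cfg.nematic_model == "director":
            bc = boundary_director(self.mesh, curve, anchoring)
            fieldp = solve_director(self.mesh, bc, self.poisson)
            if cfg.normalize_director:
                fieldp = fieldp.normalized()
            self.nematic = fieldp
        else:
            bc = boundary_q(self.mesh, curve, anchoring,
                            s_boundary=np.sqrt(2 * cfg.landau_a / cfg.landau_b))
            self.nematic = solve_qtensor(
                self.mesh, bc, a=cfg.landau_a, b=cfg.landau_b, k_q=cfg.k_q,
                poisson=self.poisson)


def step(curve: geometry.InterfaceCurve, config: SimConfig, t: float,
         ctx: _StepContext | None = None, dt_limit: float | None = None):
    """Advance the interface by one explicit step.

    Returns ``(new_curve, flow_state, dt)``.  The sequence is: resolve the
    anchoring at time t, build or reuse the mesh and operators, solve the
    nematic field and the Stokes problem, move each interface node by
    ``dt (u . n) n``, re-pin the contact points, redistribute by arclength
    (and apply the area-conservation correction), then account the
    displacement toward the remesh trigger.
    """
    if ctx is None:
        ctx = _StepContext(config)
    anchoring = config.anchoring_at(t)
    ctx.ensure(curve, anchoring)
    state = solve_stokes(ctx.mesh, curve, ctx.nematic, config.ca,
                         operator=ctx.stokes)

    u_nodes = state.velocity_vertices[ctx.mesh.curve_vertices]
    _, n_hat, _ = geometry.frame_and_curvature(curve)
    u_n = np.einsum("ni,ni->n", u_nodes, n_hat)

    ds = float(np.min(np.diff(curve.arclength)))
    dt_max = config.resolved_dt_max
    u_int = float(np.abs(u_nodes).max()) if u_nodes.size else 0.0
    dt = min(dt_max, config.cfl_factor * ds / max(u_int, 1e-12))
    if dt_limit is not None:
        dt = min(dt, dt_limit)

    # impermeable substrate: parts of the interface that bulge over the
    # pinned contacts cannot cross y = 0 and, once resting on the rigid
    # wall, stick to it (no-slip contact): wall nodes may lift off but not
    # advance.  A small mesh-resolvable clearance keeps the polyline valid.
    floor = config.wall_clearance_factor * config.h_mesh
    move = dt * u_n[:, None] * n_hat
    at_wall = curve.nodes[:, 1] <= 1.5 * floor
    sticking = at_wall & (move[:, 1] <= 0.0)
    move[sticking] = 0.0
    nodes = curve.nodes + move
    nodes[0] = geometry.CONTACT_LEFT
    nodes[-1] = geometry.CONTACT_RIGHT
    nodes[1:-1, 1] = np.maximum(nodes[1:-1, 1], floor)

    if config.conserve_area:
        # uniform normal nudge of the interior nodes restores the exact
        # area; it vanishes as the flow (and hence the drift) goes steady
        area = geometry.enclosed_area(nodes)
        s = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
        w = np.zeros(len(nodes))
        w[:-1] += 0.5 * s
        w[1:] += 0.5 * s
        w[0] = w[-1] = 0.0
        delta = (TARGET_AREA - area) / w.sum()
        interior = w > 0
        nodes[interior] += delta * n_hat[interior]
        nodes[1:-1, 1] = np.maximum(nodes[1:-1, 1], floor)

    _check_film_height(nodes, config, ctx)
    try:
        new_curve = geometry.redistribute(geometry.InterfaceCurve(nodes))
    except geometry.GeometryError as exc:
        raise SimulationError(
            f"interface became invalid at t={t + dt:.4f}: {exc}",
            curve_nodes=nodes, t=t + dt) from exc

    moved = float(np.abs(move).max())
    ctx.cum_displacement += moved
    # net normal motion of the shape this step (area corrector included;
    # a solver flux bias canceled by the corrector is not shape motion)
    disp = np.einsum("ni,ni->n", nodes - curve.nodes, n_hat)
    ctx.last_normal_speed = float(np.abs(disp).max() / dt) if dt > 0 else 0.0
    return new_curve, state, dt


def _check_film_height(nodes, config, ctx):
    """Thin central films need extra resolution to stay simulable."""
    central = (nodes[:, 0] > 0.3) & (nodes[:, 0] < 1.7)
    if not central.any():
        return
    h_min = float(nodes[central, 1].min())
    if h_min < 2.0 * config.h_mesh:
        cap = max(h_min / 2.0, 0.3 * config.h_mesh)
        if ctx.size_cap is None or cap < ctx.size_cap:
            if not config.allow_thin_film:
                warnings.warn(
                    f"interface height {h_min:.3f} under-resolved; refining "
                    "mesh (enable allow_thin_film to silence)",
                    stacklevel=3)
            ctx.size_cap = cap
            ctx.invalidate()


def steady_state_time(records, tol: float = 1e-3, window: float = 1.0,
                      t_min: float = 0.0):
    """First time t* after which the flow is steady for a full window.

    Criterion, per sample in [t*, t* + window]: the centered-difference
    rate of change of |u|_max, relative to max(|u|_max, tol), is below
    ``tol``, and the maximum interface normal speed is below ``tol``.
    Returns None if never satisfied (e.g. monotonically growing flow).
    """
    recs = list(records)
    if len(recs) < 2:
        return None
    t = np.array([r.t for r in recs])
    u = np.array([r.max_speed for r in recs])
    vn = np.array([r.max_normal_speed for r in recs])
    dudt = np.gradient(u, t)
    ok = (np.abs(dudt) / np.maximum(u, tol) < tol) & (vn < tol)
    for k in range(len(recs)):
        if t[k] < t_min:
            continue
        in_win = (t >= t[k]) & (t <= t[k] + window)
        if t[-1] < t[k] + window - 1e-9:
            break  # not enough trailing data for any later candidate
        if ok[in_win].all():
            return float(t[k])
    return None


@dataclass
class SimResult:
    config: SimConfig
    records: list
    curve: geometry.InterfaceCurve
    state: object
    ctx: _StepContext
    steady_time: float | None
    t_final: float

    @property
    def morphology(self) -> str:
        return classify_morphology(self.curve, self.config.morphology)

    def records_dataframe(self):
        import pandas as pd
        return pd.DataFrame(
            [{k: getattr(r, k) for k in DiagnosticsRecord.FIELDS}
             for r in self.records])


class Simulation:
    """Stateful integrator: supports schedules and mid-run intervention."""

    def __init__(self, config: SimConfig):
        self.config = config
        self.curve = geometry.initial_semicircle(config.resolved_n_boundary)
        self.ctx = _StepContext(config)
        self.t = 0.0
        self.records: list[DiagnosticsRecord] = []
        self.state = None
        self._next_output = 0.0
        self._last_switch = 0.0
        if config.schedule is not None:
            self._last_switch = 0.0

    # -- record keeping -----------------------------------------------------

    def _record(self, state, u_normal_max):
        cfg = self.config
        mesh, ctx = self.ctx.mesh, self.ctx
        rates = entropy_rates(state, ctx.nematic, cfg.ca)
        psi = streamfunction(state, mesh, ctx.poisson)
        n_vort, _ = vortex_census(psi, mesh)
        if cfg.nematic_model == "director":
            defects = defect_census(ctx.nematic, mesh, cfg.defect_threshold)
        else:
            # Q description: count deep minima of the scalar order parameter
            mag_field = DirectorField(
                np.column_stack([ctx.nematic.order / ctx.nematic.s_max,
                                 np.zeros(mesh.n_points)]), mesh)
            defects = defect_census(mag_field, mesh, 0.5)
        self.records.append(DiagnosticsRecord(
            t=self.t, max_speed=max_speed(state),
            area=geometry.enclosed_area(self.curve),
            asymmetry=geometry.mirror_asymmetry(self.curve),
            s_dot_v=rates.s_dot_v, s_dot_a=rates.s_dot_a,
            s_dot_tot=rates.s_dot_tot, n_vortices=n_vort,
            n_defects=len(defects),
            w_i=self.config.anchoring_at(self.t).w_i,
            max_normal_speed=float(u_normal_max)))

    # -- integration --------------------------------------------------------

    def advance_to(self, t_stop: float):
        cfg = self.config
        while self.t < t_stop - 1e-12:
            limit = t_stop - self.t
            nxt = (cfg.schedule.next_switch_after(self.t)
                   if cfg.schedule else None)
            if nxt is not None:
                limit = min(limit, nxt - self.t)
            curve, state, dt = step(self.curve, cfg, self.t,
                                    ctx=self.ctx, dt_limit=limit)
            # effective normal speed of this step, for the steady detector
            u_nmax = self.ctx.last_normal_speed
            self.curve, self.state = curve, state
            self.t += dt
            if self.t + 1e-9 >= self._next_output:
                self._record(state, u_nmax)
                self._next_output = (np.floor(self.t / cfg.output_dt) + 1) \
                    * cfg.output_dt

    def switch_w_i(self, new_w_i: int):
        """Discontinuous anchoring change; fields recompute quasi-statically."""
        cfg = self.config
        new_w_i = int(new_w_i) % 4
        if new_w_i == cfg.anchoring_at(self.t).w_i:
            return  # no-op: leave the trajectory untouched
        base_ws = cfg.schedule.w_s if cfg.schedule else cfg.w_s
        if self.t <= 1e-12:
            self.config = replace(cfg, w_i=new_w_i, schedule=None)
        else:
            if cfg.schedule is not None:
                past = [e for e in cfg.schedule.entries
                        if e[0] < self.t - 1e-12]
            else:
                past = [(0.0, cfg.w_i)]
            self.config = replace(cfg, schedule=AnchoringSchedule(
                base_ws, tuple(past) + ((self.t, new_w_i),)))
        self.ctx.config = self.config
        self.ctx.invalidate()
        self._last_switch = self.t

    def steady_time(self, t_min: float | None = None):
        cfg = self.config
        if t_min is None:
            t_min = self._last_switch_time()
        return steady_state_time(self.records, tol=cfg.steady_tol,
                                 window=cfg.steady_window, t_min=t_min)

    def _last_switch_time(self) -> float:
        if self.config.schedule is not None:
            times = [tk for tk, _ in self.config.schedule.entries
                     if tk <= self.t + 1e-12]
            return times[-1] if times else 0.0
        return 0.0

    def run(self) -> SimResult:
        cfg = self.config
        chunk = max(cfg.steady_window, 4 * cfg.output_dt)
        steady_at = None
        while self.t < cfg.t_end - 1e-12:
            self.advance_to(min(cfg.t_end, self.t + chunk))
            steady_at = self.steady_time()
            pending = (cfg.schedule.next_switch_after(self.t)
                       if cfg.schedule else None)
            if (cfg.stop_when_steady and steady_at is not None
                    and pending is None):
                break
        return SimResult(config=cfg, records=self.records, curve=self.curve,
                         state=self.state, ctx=self.ctx,
                         steady_time=steady_at, t_final=self.t)


def run(config: SimConfig) -> SimResult:
    """Integrate from the semicircular rest state to steady state or t_end."""
    return Simulation(config).run()


def apply_schedule_switch(sim: Simulation, new_w_i: int,
                          t_continue: float | None = None) -> Simulation:
    """Switch the interfacial winding number of a running simulation and
    continue integrating (to ``t_continue`` if given)."""
    sim.switch_w_i(new_w_i)
    if t_continue is not None:
        sim.advance_to(t_continue)
    return sim
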