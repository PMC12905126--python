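# activedrop

Morphodynamics of two-dimensional surface-attached active nematic drops:
a moving-boundary finite-element simulator.

Many living and synthetic fluids — bacterial suspensions, microtubule–motor
mixtures, migrating tissues — are *active nematics*: suspensions of
elongated units that align and exert force dipoles, driving flow without
external forcing. When such a fluid forms a drop pinned to a solid surface,
the interplay of orientational order, self-generated Stokes flow, and
surface tension selects a rich family of steady drop shapes and internal
vortex patterns. `activedrop` simulates this system without the thin-film
approximation, for researchers in active matter, biological physics and
soft-matter fluid dynamics.

## Model

A drop of incompressible Newtonian fluid (viscosity μ, surface tension γ,
initial radius R) is pinned to the substrate segment 0 ≤ x ≤ 2R with an
initially semicircular shape. In dimensionless form (lengths by R, time by
the viscocapillary time μR/γ, velocity by γ/μ, pressure by γ/R):

    ∇·u = 0,   0 = ∇·σ,   σ = −Π I + (∇u + ∇uᵀ) − Ca_α T,

with the *active Capillary number* Ca_α ≡ α/(γ/R) comparing the active
stress α of the suspended units to the capillary pressure (extensile for
Ca_α > 0, contractile for Ca_α < 0). The structure tensor T is either

* **p p** — a polarized director, harmonic in the bulk (strong elastic
  limit, ∇²p = 0), anchored in quarter turns relative to the boundary
  tangents: p = R(w_s π/2)·ê_x at the substrate, p = R(w_i π/2)·t̂ at the
  interface, with winding numbers w_s ∈ {0, 1}, w_i ∈ {0, 1, 2, 3}; or
* **Q** — a true nematic (Landau–de Gennes) tensor solving
  0 = [a − b tr(Q²)]Q + K_Q ∇²Q, blind to half-turn anchoring changes.

Boundary conditions: no-slip u = 0 on the substrate, capillary traction
σ·n̂ = −C n̂ on the interface (C = twice the mean curvature), the kinematic
condition (∂ₜr_i − u)·n̂ = 0, and pinned contact points. The solver is
Taylor–Hood P2/P1 on a deterministic distmesh-style triangulation, with
explicit interface advection; see `docs/methods.md` for the numerics.

## Worked example

```python
from activedrop import SimConfig, run, streamfunction, vortex_census

result = run(SimConfig(ca=-2.5, w_s=0, w_i=0, h_mesh=0.05, t_end=15.0))
print("steady at t =", result.steady_time)
print("morphology:", result.morphology)
print("max speed:", round(result.records[-1].max_speed, 4))
psi = streamfunction(result.state, result.ctx.mesh, result.ctx.poisson)
n, cells = vortex_census(psi, result.ctx.mesh)
print("vortices:", n, [round(v, 5) for _, v in cells])
```

prints

```
steady at t = 4.759999999999984
morphology: simple-symmetric
max speed: 0.0586
vortices: 2 [0.01029, -0.01028]
```

A contractile drop with tangential anchoring (w_s = w_i = 0) reaches its
steady state after about five viscocapillary times, keeps its mirror
symmetry, and sustains one pair of counter-rotating vortices (the two
streamfunction extrema of opposite sign); the maximum internal speed is
about 0.06 γ/μ at this activity.

The same study from the shell:

```sh
activedrop run --ca -2.5 --ws 0 --wi 0 --out runs/contractile
activedrop sweep --ca-grid -5.5,-2.5,2.5,5.5 --anchoring-grid 0:0,0:1,0:2 \
    --out runs/state_diagram
activedrop protocol --ca 2.5 --schedule 0:0,11:1,40:0 --out runs/cycle
```

`run` writes a diagnostics time series (CSV), the final interface polyline
(CSV), a VTK snapshot of the fields, and a manifest with the resolved
configuration and output checksums; `sweep` aggregates a morphology state
diagram over activity and anchoring; `protocol` changes the interfacial
anchoring during the run (the drop's shape and flow can be switched and
reversibly recovered this way).

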