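# Methods

## Model

`activedrop` integrates the morphodynamics of a two-dimensional drop of
active nematic fluid pinned to a rigid, impermeable substrate.  The drop
occupies the region between the substrate segment `0 <= x <= 2` (lengths in
units of the initial radius R) and a free liquid–air interface that starts
as the unit semicircle.  All quantities are dimensionless: lengths by R,
time by the viscocapillary time mu R / gamma, velocity by gamma / mu,
pressure and stress by the capillary pressure gamma / R.

The fluid is an incompressible Stokes flow,

    div u = 0,      0 = div sigma,
    sigma = -Pi I + (grad u + grad u^T) - Ca_alpha T,

where the single flow parameter is the active Capillary number
`Ca_alpha = alpha R / gamma` (extensile for Ca > 0, contractile for Ca < 0)
and T is the structure tensor of the suspended active units:

* **director model** — T = p p, with p the polarized orientation field.
  In the strong elastic limit the order relaxes instantaneously, making
  each Cartesian component of p harmonic (`laplacian p = 0`) with Dirichlet
  anchoring data: `p = R(w_s pi/2) e_x` on the substrate and
  `p = R(w_i pi/2) t_hat` on the interface.  The winding numbers
  `w_s in {0, 1}`, `w_i in {0, 1, 2, 3}` count counterclockwise quarter
  turns relative to the local tangent.  No unit-norm constraint is imposed
  in the bulk (an optional `normalize_director` flag renormalizes
  `p / max(|p|, 0.1)` for sensitivity studies): |p| <= 1 by the maximum
  principle and |p| dips at defects, which regularizes the active stress
  there.
* **Q-tensor model** — T = Q, the stationary Landau–de Gennes tensor
  solving `0 = [a - b tr(Q^2)] Q + K_Q laplacian Q` with strong anchoring
  `Q = S_max (p_b p_b - I/2)` built from the same boundary director.  This
  description respects the head–tail symmetry, so anchoring pairs that
  differ by half turns (w and w+2) are identical.

Boundary conditions for the flow: no-slip `u = 0` on the substrate
(including the two contact-point vertices), capillary traction
`sigma . n_hat = -C n_hat` on the interface (C = twice the mean curvature,
+1 on the initial semicircle, with the outward normal convention), and the
kinematic condition `(d r_i/dt - u) . n_hat = 0` moving the interface.
The contact line is pinned at (0, 0) and (2, 0) for all time.

## Discretization

* **Interface.** An ordered polyline (spacing ~ h_mesh), the only
  dynamical state.  Tangents by centered chords, curvature by the
  three-point circumscribed circle (one-sided at the pinned endpoints,
  where curvature is used only for diagnostics).  After each step the
  nodes are re-placed at equal arclength; a uniform second-order normal
  nudge restores the enclosed area exactly (area is the conserved quantity
  of the incompressible dynamics).
* **Mesh.** A force-equilibrium (distmesh-style) triangulation built on
  `scipy.spatial.Delaunay`, with edge lengths graded from `0.25 h_mesh` at
  the contact points to `h_mesh` beyond distance 0.2, resolving the corner
  stress singularity and the anchoring-mismatch boundary defects.  Interior
  seeds come from a deterministic RNG keyed by the configured mesh seed,
  so runs are bit-reproducible.  Minimum triangle angle >= 15 degrees is
  enforced with cleanup/retry passes.
* **Flow.** Taylor–Hood P2/P1 mixed elements — the standard inf-sup-stable
  pair, no stabilization.  The active stress enters the weak form as
  `Ca int T : grad v` on the right-hand side with T interpolated from the
  nodal nematic field; the capillary traction is the natural boundary term
  on interface edges, assembled with 3-point Gauss quadrature from the
  current interface polyline.  The traction condition fixes the pressure
  level, so the saddle system is nonsingular and solved by sparse LU.
  Incompressibility holds in the weak (P1-projected) sense to solver
  precision; the pointwise L2 divergence of any Taylor–Hood solution is
  O(h^2) and is reported separately.
* **Nematic.** P1 elements.  The director solve is two Dirichlet–Poisson
  solves sharing one factorization (also reused by the streamfunction and
  the Q-tensor initialization).  The Q-tensor equation uses mass-lumped
  reaction terms and a damped Newton iteration started from the harmonic
  extension of the boundary data, with a semi-implicit gradient-flow
  fallback on stagnation; nonlinear residual tolerance 1e-8.
* **Time stepping.** Explicit first order.
  `dt = min(dt_max, cfl * ds / max |u|_interface)` with `dt_max = 0.4
  h_mesh` by default — explicit capillary forcing is stable for dt of the
  order of the node spacing in viscocapillary units, and 0.4 keeps a
  margin.  Interface nodes move only along their normals (tangential
  motion is a reparameterization handled by the redistribution).  Between
  remeshes the factorized Stokes operator and the nematic field are
  reused; the traction right-hand side is rebuilt from the moving polyline
  every step, which retains the stabilizing capillary feedback.  A remesh
  triggers when the accumulated boundary displacement exceeds
  `0.2 h_mesh` or the anchoring changes.

## Contact constraint at the wall

At strong extensile activity (Ca >= ~4.5) the corner outflow rolls the
interface over the pinned contact points.  The substrate is impermeable,
so the overhanging interface cannot cross y = 0: interface nodes are
clamped to a small clearance above the wall (`wall_clearance_factor *
h_mesh`, default 0.05).  This models fluid resting on the wall beyond the
pins without depinning the contact line; contact-line motion itself is out
of scope.  Runs whose interface would self-intersect abort with the
offending state attached to the exception.

## Diagnostics

* **Steady-state detector.**  t* is the first record time such that for
  every sample in `[t*, t* + 1]` the centered-difference rate of change of
  `|u|_max`, relative to `max(|u|_max, tol)`, stays below `tol = 1e-3`,
  and the maximum interface normal speed stays below tol.  The window and
  tolerance make "reaches steady state by t = 10" an operational
  statement; note that for signals decaying to zero the criterion is
  strict (it first holds when the signal falls below tol^2).
* **Entropy production.**  `s_v = int (grad u + grad u^T) : grad u dA >= 0`
  (viscous, positive-definite by construction) and
  `s_a = -Ca int T : grad u dA` (active work), by element quadrature exact
  for the discrete polynomial degrees; the pressure term vanishes by
  incompressibility so the total is their sum.  At an exact steady state
  the divergence theorem forces `s_v + s_a = -int C u.n ds -> 0`; only the
  robust claims (positivity, quadratic small-Ca scaling, s_a < 0) are
  meaningful observables of the decomposition.
* **Vortex census.**  Interior extrema of the streamfunction (psi = 0 on
  the whole boundary, `laplacian psi = -omega`), keeping extrema above 5%
  of max |psi| and merging within `2 h_mesh`; the extremum sign gives the
  rotation sense.
* **Defect census.**  Local minima of |p| below a threshold, merged within
  `2 h_mesh`; a two-ring minimum test suppresses shallow grading
  artifacts.  The default threshold 0.8 sits above the `1/sqrt(2)` floor
  of the 90-degree anchoring-mismatch boundary defects at the contact
  points (a converged finite-difference oracle puts the next landscape
  feature near 0.93) and well above the near-zero cores of 180-degree
  mismatches and bulk vortex defects.
* **Morphology classifier.**  Fixed, config-exposed thresholds replace
  visual classification: film-two-lobes if the interface height over
  `x in [0.8, 1.2]` falls below 0.25 of the maximum height with at least
  two height maxima; broken-symmetry if the mirror asymmetry (area of the
  symmetric difference with the x -> 2-x reflection over the drop area)
  exceeds 0.01; mushroom if the width above half height exceeds the
  contact-line width by more than 5%.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `h_mesh` | 0.05 | target edge length (drop radii); ~6-7k velocity unknowns |
| `dt_max` | `0.4 h_mesh` | explicit capillary stability margin |
| `cfl_factor` | 0.5 | advective CFL fraction |
| `steady_tol` | 1e-3 | steady detector tolerance per unit time |
| `a, b` | 1, 2 | Landau coefficients (S_max = 1) |
| `K_Q` | 2.5e-3 | nematic coherence length sqrt(K_Q/a) = 0.05 |
| `output_dt` | 0.25 | diagnostics cadence |
| `t_end` | 50 | matches the anchoring-protocol span |

The Landau parameters are not fixed by the continuum model (only S_max and
the coherence length matter); the defaults make defect cores resolvable at
the default mesh spacing, and parameter sensitivity should be assessed by
rerunning with the config-exposed values rather than assumed.

## Problem sizes used by the shipped studies

The acceptance script runs the anchoring protocol at h = 0.05 (the
reference resolution, ~6-7k velocity unknowns) and the small-activity
scaling study at h = 0.08; the state-diagram sweep in the test suite runs
at h = 0.1 with t_end = 20.  These sizes resolve the reported observables
(vortex counts, defect counts, scaling exponents, steady timings) — the
morphology boundaries shift by O(h) in Ca, which is within the tolerance
of the reported thresholds.

## Known limitations

* First-order time integration; the explicit capillary step limits dt to
  O(h).  A semi-implicit traction variant is a config flag for stiff runs.
* Quasi-static nematic order only: advection and co-rotation of p or Q
  (finite rotational viscosity) are not modeled.
* The film-plus-lobes states at strong extensile activity interact with
  the wall-contact constraint beyond the pins; their detailed shape near
  the contacts is resolution-sensitive even though the film transition
  itself is robust.
* Topology change (film pinch-off, coalescence) is detected as run
  termination, not simulated through.
* Odd interfacial winding numbers force a -1/2 bulk defect in the
  Q-tensor description; if its core (coherence length sqrt(K_Q/a)) is not
  resolved by the mesh, the discrete defect can sit asymmetrically and
  artificially break the mirror symmetry that the nematic description
  should preserve.  Choose K_Q so that sqrt(K_Q/a) >~ 1.5 h_mesh.
* The steady-state detector's absolute branches make a passive drop
  (|u| at the discretization noise floor) register steady only after a
  few viscocapillary times, although its shape is stationary from t = 0.
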