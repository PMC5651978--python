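# Methods note

This note records the model equations, the parameter choices with units and
rationale, the scope of the synthetic-data generator, the numerical choices,
and the known limitations of `evacdem`.

## Model

### Bodies

Agents are soft two-dimensional ellipses with semi-major axis `a` along the
body axis and semi-minor axis `b`. The default body (a = 0.03 m, b = 0.015 m,
mass m = 0.030 kg) is a mouse-scale footprint. Orientation is not integrated
from a moment equation; instead the body axis relaxes exponentially toward
the direction of motion with time constant `rotation_time` (see *Numerical
choices*).

### Equation of motion

Each agent obeys

    m dv/dt = F_psy + Σ F_contact

with no explicit friction against the ground (the psychological force already
relaxes velocity toward a finite desired velocity, which bounds speeds).

**Psychological force.** `F_psy = (m / Δt_res)(v* − v⁰)`, where `v*` is the
desired velocity and `Δt_res = 0.1 s` the response time. The gain
`c = m / Δt_res` is always derived from the agent's mass, so an isolated
agent relaxes from rest to its desired speed as `v(t) = v*(1 − e^{−t/Δt_res})`
regardless of scale. An equivalent formulation in the frame rotated so that
the desired velocity has no transverse component is provided
(`psychological_force_rotated`) and tested to compose to the same global
vector.

**Contact force.** Normal direction: linear spring–dashpot,
`F_n = (k_n δ − η (v_rel · n̂)) n̂`, with penetration depth δ and the normal
pointing from the other body toward the subject. The dashpot coefficient is
derived from the coefficient of restitution e:

    η = 2 (−ln e) √(m_eff k_n) / √(π² + ln² e)

which makes the half-period rebound of the linear oscillator come out exactly
at relative-speed ratio e (`test_analytic_rebound_of_damped_oscillator`).
Tangential direction: a Coulomb-capped tangential spring (Cundall–Strack).
The tangential stretch ξ accumulates relative tangential displacement over
the contact's lifetime, is projected into the current tangent plane, and the
force `−k_t ξ` is capped at `μ |F_n|`; when the cap binds, the stretch is
reset to the cap (sliding). The stretch is zeroed when a contact breaks.

### Penetration depth of two ellipses

Ellipse i's boundary is parametrized by angle t and substituted into ellipse
j's implicit quadratic, giving
`g(t) = A cos²t + B sin t cos t + C sin²t + D cos t + E sin t + F`. With
u = tan(t/2) this becomes a quartic whose real roots (companion-matrix
eigenvalues, Newton-polished; the u → ∞ root t = π is handled when the
leading coefficient vanishes) are the boundary crossings. The chord joins the
two most separated crossings; δ is the width of the overlap lens measured
along the mid-normal of that chord (the two line–ellipse intervals are
intersected). In the circle limit this reduces exactly to `2r − d`. If the
boundaries do not cross but one center lies inside the other body (deep
overlap), δ falls back to the center-line sum of support radii minus the
center distance. A brute-force oracle (`overlap_oracle`: dense boundary
sampling + bisection) recomputes the same quantity independently and agrees
with the kernel within 1e-4 m on hundreds of random pairs (in practice to
~1e-7 m; the residual is the oracle's sampling resolution).

Walls are thin two-sided segments. The deepest boundary point against the
wall line is found in closed form from the ellipse quadratic; if it projects
beyond the segment, the near endpoint acts as a point obstacle with a
center-to-corner normal. At θ = 0 the guide walls are collinear with the exit
wall, so the top wall is shortened to tile exactly with them and avoid
double-counted contacts.

### Behavioural rules

Every agent rushes toward the exit-gap midpoint at its desired speed.
Decisions are re-evaluated every calculation step Δt:

- **Overtaking.** If the nearest agent in the front sector is currently
  slower than oneself, the agent tries to steer ±π/6 into a side sector.
  Sectors are circular sectors of half-width π/6, radius `4a` (0.12 m),
  with axes rotated {0, +π/6, −π/6} from the exit-bound heading; sector
  area is πR²/6.
- **Handedness.** 90% of agents probe the +π/6 sector first, the rest the
  −π/6 sector (assigned exactly, seeded).
- **Critical density.** A sector is rejected when its occupant density
  reaches `ρ_c = 77 agents/m²` (mouse scale: one sector occupant is
  132 m⁻², so any occupied side sector is rejected — occupancy acts as a
  binary gate at these parameters).
- **Following.** If both side sectors are rejected, the agent heads toward
  the blocker at the blocker's current speed (capped at its own desired
  speed).
- **Wall avoidance.** Within a clearance `2b` of the nearest wall the bare
  direction is blended with the away-from-wall direction, weighted
  `1 − d/d_avoid`, and renormalized.

### Arena

A 0.4 m × 0.6 m room with a 0.06 m exit gap centered in the top wall. Two
0.15 m guide walls hinge at the gap edges, rotated θ ∈ [0°, 90°) from the
exit-wall plane into the room, symmetric about the exit centerline. Agents
start in a 0.25 m deep waiting area at the bottom, placed by seeded rejection
sampling with all bodies vertical and non-overlapping; agents whose centers
cross the exit line inside the gap are removed with a linearly interpolated
exit time.

## Parameters

| Parameter | Symbol | Default | Units | Why |
|---|---|---|---|---|
| body semi-axes | a, b | 0.03, 0.015 | m | mouse-scale footprint, 2:1 aspect |
| mass | m | 0.030 | kg | mouse scale |
| normal/tangential spring | k_n, k_t | 5.0e4 | N/m | stiff penalty contact; overlaps stay ≤ 1e-4 m under crowd pressure |
| restitution | e | 0.1 | – | strongly dissipative bodies; sets η via the formula above |
| friction coefficient | μ | 0.1 | – | weak Coulomb cap on the tangential spring |
| response time | Δt_res | 0.1 | s | velocity relaxation; gain c = m/Δt_res = 0.3 kg/s at mouse mass |
| rotation time | – | 0.1 | s | body-axis relaxation; matches Δt_res (see *Numerical choices*) |
| desired speed mean | – | 0.4 | m/s | unhurried rodent locomotion scale |
| speed sd profile | S_mice | 0.12 → 0.03 | m/s | decreases with θ (0.12, 0.10, 0.08, 0.06, 0.045, 0.03 at 0°–75°); uniform mode uses the mean of these |
| critical density | ρ_c | 77 | m⁻² | ≈ 11% body-area coverage at mouse scale |
| sector radius | R | 4a = 0.12 | m | four body lengths of look-ahead |
| wall clearance | d_avoid | 2b = 0.03 | m | one body width |
| room, exit, guide walls | – | 0.4×0.6, 0.06, 0.15 | m | funnel geometry with θ the swept variable |
| waiting depth | – | 0.25 | m | placement feasibility: 20 vertical bodies fit comfortably below the random-packing limit |
| calculation step | Δt | 1e-3 | s | decision cadence |
| physics sub-steps | – | 4 | – | stability (below) |
| recording stride | – | 33 | steps | ≈ 30 Hz frames, video-tracking-like |

## Synthetic track generator — scope

`evacdem.synthetic` emulates the *structure* of video-tracked trials
(N agents × C cases × E angles at a fixed frame interval) with straight-line
trajectories at prescribed constant speeds truncated at prescribed exit
times. Because every speed and exit time is prescribed, all evacuation
metrics have exact closed forms, returned alongside the data; the generator
is an oracle for the measurement layer, not a model of the dynamics.
Optional position jitter perturbs the written tracks only, never the closed
forms. The `fis_preset` bundles a faster-is-slower-shaped parameterization
(speed means, dispersions, and last-exit times all decreasing with angle).
Generator parameters were fixed before the measurement tests were run and
are never adjusted to make tests pass.

## Numerical choices

- **Integrator.** Semi-implicit (symplectic) Euler per agent: velocity from
  the summed force, then position from the new velocity.
- **Sub-stepping.** The stiff contact spring (ω₀ = √(k_n/m_eff) ≈ 1.8e3 s⁻¹
  at pair effective mass 0.015 kg) is unstable at the decision step
  Δt = 1e-3 s (spectral radius ≈ 3.8). Physics therefore runs on 4 sub-steps
  (h = 2.5e-4 s, ω₀h ≈ 0.46) per decision step, with desired velocities held
  fixed across the sub-steps.
- **Orientation relaxation.** Slaving the body axis instantaneously to the
  velocity direction is not integrable at finite spring stiffness: a
  direction change rotates the 0.03 m semi-major axis into neighbours within
  one sub-step, conjuring millimetre-deep overlaps whose spring energy is
  injected from nowhere (observed as 30 g bodies flung at several m/s).
  The axis instead relaxes toward the heading (shortest π-periodic
  difference) with time constant 0.1 s, bounding the rotation-induced
  boundary displacement per sub-step to ~1e-4 m.
- **Quartic roots.** Complex companion-matrix eigenvalues with an imaginary
  tolerance of 1e-7·(1+|λ|), Newton polish on g(t), duplicate-point merging,
  and the t = π special case.
- **Speeds from tracks.** Instantaneous speeds are central differences of
  positions (one-sided at the ends, `np.gradient`), since tracking exports
  carry positions, not velocities.
- **Determinism.** All randomness flows from `numpy` `SeedSequence`; sweep
  trial seeds are spawned children reduced below 2³¹. Reruns are bit-identical
  (asserted in the test suite).
- **Complexity.** Contact detection is all-pairs O(N²) per sub-step; at the
  study scale (N = 20) this is faster than maintaining a neighbour grid.

## Limitations

- No rotational inertia or contact torques; orientation is kinematically
  slaved to the heading.
- All-pairs contact detection limits practical runs to a few hundred agents.
- The thin two-sided walls can in principle be tunnelled through by a
  sufficiently fast body (not observed at study parameters, where maximum
  speeds stay below ~0.7 m/s).
- The critical-density rule is effectively binary at mouse scale (one
  occupant saturates a sector), so the behavioural layer reduces to
  "steer to the unoccupied side, else follow".
- Body contact does not model the deformability or limb articulation of real
  animals; restitution and friction values are effective parameters.
- Measured speed dispersion per angle is an outcome of the dynamics and does
  not numerically equal the imposed desired-speed dispersion profile; only
  the qualitative contrast between the angle-dependent and uniform modes is
  meaningful.
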