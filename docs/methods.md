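# Methods

## Model

The model captures the vertical and roll dynamics of a trotting quadruped
in the transverse plane. Two rigid bodies — fore (F) and hind (H) — are
joined at their common centre of mass by a frictionless joint with a
torsional spring; four massless, vertical spring legs hang from the bodies
at lateral distance `D` from the midline. Legs are force-free in swing and
exert a linear spring force along their (vertical) axis in stance; they
touch down and lift off exactly at the nominal length, so contact
transitions exchange no energy and the model is conservative. Horizontal
translation, pitch, leg mass, damping and actuation are all outside the
model's scope.

Quantities are non-dimensionalized by total mass `M`, length `D` and time
`√(D/g)`. The parameter bundle is:

| parameter | meaning | dog | horse |
|---|---|---|---|
| `μ0` | mean body roll inertia `(I_F+I_H)/(2MD²)` | 0.62 | 0.72 |
| `ε_μ` | fore-aft inertia asymmetry | 0.12 | 0.14 |
| `k0` | mean leg stiffness `(K_F+K_H)D/(2Mg)` | 1.5 | 2.2 |
| `ε_k` | fore-aft leg-stiffness asymmetry | 0.21 | 0.25 |
| `κ` | torsional/leg stiffness ratio `k_B/k0` | 0.20 | 0.21 |
| `z*` | apex height offset of the periodic orbit | 0.06 | 0.06 |

The presets derive from published morphometric and gait measurements of
large-breed dogs and warmblood horses; `k0`, `κ` and `z*` are calibration
products (below). Two internal inconsistencies of the source tables are
worth recording. First, the dog's physical rows (M = 35 kg,
I_F + I_H = 0.43 kg·m², D = 0.10 m) give μ0 = 0.614, which rounds to 0.61
rather than the reported 0.62; the tests use a 0.01 band for this quantity.
Second, the asymmetry fractions implied by the physical rows
((I_F−I_H)/(I_F+I_H) ≈ 0.21 dog / 0.25 horse; the stiffness ratios imply
≈ 0.12 / 0.14) are swapped relative to the labelled ε_μ/ε_k values; the
labelled values are taken as authoritative, and they are the ones that
reproduce the fore-led footfall pattern (Sequence 5) that real dogs and
horses show.

## Hybrid integration

A half cycle starts at a flight apex (`ż = 0`) immediately after the
left-right reversal and is integrated phase by phase through the contact
automaton (flight, fore stance, hind stance, double stance). Within each
phase the smooth dynamics are integrated with an adaptive high-order
Runge-Kutta method (DOP853, rtol 1e-10 / atol 1e-12 by default; sweeps and
calibration use 1e-9 / 1e-11). Guard functions `r_F = z + sin θ_F`,
`r_H = z − sin θ_H` and `r_A = ż` are monitored as integrator events:
touchdowns fire only on descending zero crossings and liftoffs only on
ascending ones, which prevents chattering at grazing contact. A guard that
is already at zero and moving through it in the admissible direction fires
immediately — this is what resolves exactly simultaneous pair touchdowns
(the symmetric model) without loss of precision. Each leg of the active
diagonal pair must touch down exactly once and a double-stance interval
must exist; trajectories that leave this automaton (e.g. aerial
re-contact, or a liftoff into descending flight with no apex) raise typed
errors rather than being simulated further.

The inactive diagonal pair never enters the dynamics between reversals,
but its mirrored tip heights (`z − sin θ_F`, `z + sin θ_H`) are monitored,
and a negative excursion sets a violation flag on the result.

Footfall classification: touchdown (liftoff) pairs closer than
`tol_sim = 1e-6` time units are merged into a simultaneous event, and the
resulting phase path is mapped to one of the nine admissible trot
sequences. The band is needed because exact simultaneity (Sequence 1) is
measure-zero in the asymmetric model; 1e-6 is far below the gait timescale
(~1.7) and far above the event-location error (~1e-12).

Energy conservation serves as a global integration check: drift per half
cycle stays below 1e-8 at default tolerances (typically ~1e-11), and the
test suite cross-checks all event times of three presets against an
independent fixed-step RK4 integrator with bisection event refinement.

## Periodic solutions and stability

The Poincaré section is the post-reversal apex; the return map `P` is one
half cycle plus reversal. The apex height `z*` is prescribed — it selects
the energy level along the one-parameter family of orbits — so the fixed
point solve runs over the four roll coordinates with `z` pinned, using
damped least squares (Levenberg-Marquardt, forward-difference steps 1e-6)
on all five residual components of `x − P(x)`; conservation makes the
fifth component vanish at a solution of the other four. A solution is
accepted when the max-norm residual is below 1e-8. For the symmetric model
the solve is restricted to the anti-symmetric subspace
(`θ_F = −θ_H`, `θ̇_F = −θ̇_H`), which is invariant under `P` and contains
the trotting solution; seeds come from a deterministic coarse grid
(`θ_F ∈ [0.05, 0.6]` × `θ̇_F ∈ [−1.5, 0]`). Asymmetric solves are seeded
by continuation from a neighbouring solution, with the grid ladder as
fallback — continuation steps are kept at or below 0.02 in the asymmetry
fractions, because larger seeding jumps can strand the solver on gait
failures.

The Jacobian of `P` is computed by central finite differences
(per-component step `1e-6·max(1, |x_j|)`; a Richardson check in the test
suite confirms second-order consistency). Because the system is
conservative and the orbit lives in a one-parameter family, one eigenvalue
always sits at 1; stability therefore uses a tolerance band,
`stable ⇔ Λ ≤ 1 + 1e-3`, with the same band absorbing finite-difference
noise around the unit eigenvalue.

## Gait characteristics

The full gait cycle is two mirrored half cycles, so all characteristics
come from one half cycle: `τ*` is the apex-to-apex duration; `δ_z` the
peak-to-peak excursion of `z`; duty factors are stance duration over the
full cycle `2τ*`, with `β0` the fore/hind mean (equal to the four-leg mean
by left-right symmetry); peak ground reaction forces are maxima of `|f|`
in body-weight units; roll amplitudes are `max |θ|` over the cycle (half
the peak-to-peak excursion, by the cycle's mirror symmetry), reported in
degrees. Extrema are read off a dense sampling (~4000 points) of the
piecewise interpolant; for these smooth phases the sampling error is below
1e-6. The peak-to-peak convention for `δ_z` and the `max |θ|` convention
for roll are the ones consistent with the reference characteristics table
(0.12 and 29° for the dog).

## Calibration

`(k0, κ, z*)` of the symmetric model are fitted to measured fast-trot
statistics (Froude number ≈ 1.3) by minimizing

    V = c1 (τ* − τ̄*)² + c2 (δ_z − δ̄_z)² + c3 (β0 − β̄0)²,

with weights (0.1, 1, 1) — the duration target is numerically larger than
the other two. Targets: dog τ̄* = 1.9, δ̄_z = 0.11, β̄0 = 0.46; horse
τ̄* = 1.7, δ̄_z = 0.11, β̄0 = 0.4. The optimizer is a derivative-free
Nelder-Mead simplex in box-scaled coordinates, multistarted from a 3×3×3
grid over `k0 ∈ [0.5, 4]`, `κ ∈ [0.05, 0.6]`, `z* ∈ [0.02, 0.12]`
(gradients are unavailable and the inner periodic solve adds ~1e-9 noise),
stopping at simplex diameter 1e-4; failed inner solves receive a large
penalty. Inner solves are warm-started from the previous fixed point.

A structural finding, visible in `examples/04`: V is a shallow curved
valley in which quite different triples fit the three statistics almost
equally well (for the dog, V ≈ 0.0025 at (1.5, 0.20, 0.06) but decreases
monotonically away from it toward larger κ, reaching ≈ 0.0007 at the box
boundary). The reported optimum is therefore box-dependent, and this
implementation's full-box optimum for the dog, (0.95, 0.60, 0.083), does
not coincide with the reference values (1.5, 0.20, 0.06), which are not a
local minimum of V under this implementation's characteristics.

## Asymmetry-plane sweeps

Sequence and stability maps solve each grid cell by row-major continuation
from the symmetric origin. The slope `a` of the Sequence-1 line is found
per `ε_k` by marching `ε_μ` upward in steps of 0.02 until the signed
fore-hind touchdown split changes sign, bisecting to 1e-4, and fitting a
line through the origin by least squares (dog base: a = 0.695, residual
~2e-5; the slope drops to 0.59 when κ is raised 50%). The band half-width
`b` bisects the `Λ = 1 + 1e-3` crossing on both sides of the line at probe
`ε_k` values and averages the distances; `b = 0` when the line itself is
stable, and a crossing that leaves the parameter box is reported as an
infinite band. The symmetric-model critical `μ0` is bisected per `κ` the
same way and lands near the linear-analysis boundary `μ0 = κ + 1/2`
(0.659 at k0 = 1.5, κ = 0.2; 0.725 at k0 = 2.2, κ = 0.21 — the test suite
computes both).

## Known limitations

* The horse preset sits on a stability knife edge: the critical `μ0` at
  (k0 = 2.2, κ = 0.21, z* = 0.06) lies between 0.72 and 0.73, and at the
  two-decimal preset `μ0 = 0.72` the symmetric horse model comes out
  marginally stable (Λ = 1 within 1e-3), so the unstable-band width at the
  horse base evaluates to b = 0. Classification at this point is sensitive
  to rounding in the calibrated parameters — at κ = 0.195, or μ0 = 0.73,
  the same model is clearly unstable (Λ > 1.05; the test suite computes
  all three points) — so the b > 0 phenomenon should be probed slightly
  above the boundary, not exactly at the preset.
* Calibration optima are box-dependent (see above); the printed-precision
  reference triples are reproduced by construction only as presets, not as
  V-minima.
* Roll amplitudes (~29° dog, ~19° horse) far exceed measured trunk roll of
  trotting animals (~5-6°): the model has no muscle or joint structure
  limiting leg abduction, a known idealization of smooth rotational leg
  roots.
* No synthetic-data generator is involved anywhere: all inputs are the
  dimensionless parameter presets; passing tests demonstrate properties of
  the model, not of measured animal data.
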