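# quadtrot

Transverse-plane dynamics of quadrupedal trotting: a hybrid-dynamics model
of two rigid bodies and four spring legs, with periodic-orbit search,
Floquet-type stability analysis, calibration to animal gait statistics, and
parameter sweeps over fore-aft asymmetry.

## The scientific problem

Quadrupeds such as dogs and horses are fore-aft asymmetric: the front of
the body is heavier and has a larger roll inertia, and the fore legs are
stiffer than the hind legs. During trotting, diagonal leg pairs touch down
alternately and each touchdown exerts opposite roll moments on the fore and
hind parts of the trunk. This package models those roll-and-bounce dynamics
in the transverse plane and asks how fore-aft asymmetry changes (i) the
footfall pattern within a trot step and (ii) the orbital stability of
steady trotting.

The model consists of two rigid bodies (fore body F, hind body H) joined at
their common centre of mass by a torsional spring of stiffness `K_B`, each
carrying a left and a right massless leg spring (`K_F`, `K_H`) at distance
`D` from the midline. Writing `z = (Z − L0)/D` for the dimensionless COM
height and `θ_F`, `θ_H` for the body roll angles, the dimensionless
equations of motion are

    z̈ + Σ f_ij + 1 = 0
    μ_i θ̈_i + Σ_j d_j f_ij cos θ_i + k_B (θ_i − θ_ī) = 0,   i ∈ {F, H}

with leg forces `f_ij = k_i (z + d_j sin θ_i)` during stance and 0 during
swing (`d_L = +1`, `d_R = −1`). A leg touches down and lifts off when its
length passes the nominal length, i.e. at `r_ij = z + d_j sin θ_i = 0`, so
the model conserves energy. Fore-aft asymmetry enters through

    μ_F = (1+ε_μ) μ0,  μ_H = (1−ε_μ) μ0,  k_F = (1+ε_k) k0,  k_H = (1−ε_k) k0,

with `κ = k_B/k0` the torsional-to-leg stiffness ratio.

Steady trotting is a fixed point `x* = P(x*)` of the apex return map `P`
(one apex-to-apex half cycle followed by the left-right reversal
`B_LR = diag(1, −1, −1, 1, −1, −1)`), computed on the section
`x = [z, θ_F, θ_H, θ̇_F, θ̇_H]` with `ż = 0`. Stability is judged by
`Λ = max_i |λ_i|` of the Jacobian of `P` at `x*`: the system is
conservative, so `Λ = 1` (marginal) is the best attainable; `Λ > 1` is
unstable.

## Worked example

```python
from quadtrot import analyze_stability, compute_characteristics, find_periodic, preset

params, z_star = preset("dog")    # μ0=0.62, ε_μ=0.12, ε_k=0.21, k0=1.5, κ=0.20, z*=0.06
sol = analyze_stability(find_periodic(params, z_star))
print(sol.sequence.sequence_id, round(sol.tau_half, 4), round(sol.Lambda, 6))
ch = compute_characteristics(sol)
print(round(ch.duty_fore, 3), round(ch.duty_hind, 3),
      round(ch.grf_max_fore, 3), round(ch.grf_max_hind, 3))
```

prints

```
5 1.7538 1.0
0.465 0.462 1.069 0.645
```

meaning: the dog preset trots with Sequence 5 (the fore leg of the diagonal
pair touches down first and lifts off last — the footfall pattern dogs
actually use), the half cycle lasts 1.754 time units (`√(D/g)` ≈ 0.101 s,
so ≈ 0.18 s), the orbit is marginally stable (Λ = 1), the fore duty factor
exceeds the hind one, and the fore leg carries the larger peak ground
reaction force (1.07 vs 0.65 body weights).

The `examples/` directory walks through each capability: half-cycle
simulation and the event log, periodic orbits and eigenvalues, the
characteristics table, calibration, sequence/stability maps over the
`(ε_k, ε_μ)` plane, and the boundary estimates (slope `a` of the
simultaneous-touchdown line, band half-width `b`, and the symmetric-model
stability boundary near `μ0 = κ + 1/2`).

A thin CLI mirrors the library:

```sh
quadtrot find-orbit --preset dog
quadtrot characteristics --preset horse
quadtrot sweep --map sequence --preset dog --grid 0 0.3 7
quadtrot estimate-a --preset dog
```

## Layout

- `src/quadtrot/params.py` — parameter bundles, non-dimensionalization, presets
- `src/quadtrot/dynamics.py` — continuous dynamics, guards, energy
- `src/quadtrot/hybrid.py` — event-driven half-cycle integration and sequence classification
- `src/quadtrot/periodic.py` — apex return map, fixed points, Floquet-type stability
- `src/quadtrot/metrics.py` — gait characteristics
- `src/quadtrot/calibrate.py` — fitting (k0, κ, z*) to animal statistics
- `src/quadtrot/sweeps.py` — asymmetry-plane maps and boundary estimates
- `src/quadtrot/cli.py`, `src/quadtrot/io.py` — command line and writers

See `docs/methods.md` for the modelling and numerical details.
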