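# Methods

`motorcargo` simulates a rigid spherical cargo hauled along cylindrical
microtubules by elastic motor proteins, with the cargo subject to
overdamped translational and rotational Brownian motion. This note
documents the model, its numerical treatment, the default parameters,
and the limits of what the simulations can show.

## Model

**Cargo.** A rigid sphere of radius `R` (nm). State: center position
`r` (lab frame) and orientation quaternion `q` (body→lab). The lab
frame has the microtubule axis along +y, z up, x lateral. Units
throughout: nm, s, pN, pN·nm.

**Microtubules.** Cylinders of radius 12.5 nm parallel to y at z = 0,
either a single one at x = 0, an explicit list of x offsets, or an
infinite evenly spaced array realized by periodic wrapping of the cargo
x coordinate. Binding sites sit every 8 nm along the axis; the surface
point of a site is taken in the half-plane of the approaching motor
anchor, so the anchor→site distance is `hypot(rad2d − 12.5, Δy)` where
`rad2d` is the anchor's distance to the axis.

**Motors.** Each motor is anchored at a fixed point on the sphere
surface (a unit vector in the body frame) and modeled as a cable
("bungee") spring: tension `k·(ext − L0)` when its effective length
exceeds the rest length `L0`, zero force when shorter. A bound motor's
head is point-located at its binding-site surface point.

**Cargo excluded volume on the cable.** The cable cannot pass through
the cargo. If a binding site lies on or above the tangent plane at the
anchor, the path is the straight segment; otherwise the shortest
sphere-avoiding path is used: a geodesic arc from the anchor to the
tangent point plus the straight tangent segment to the site. The
effective length enters both the reach test and the tension; for a
wrapped cable the pull on the cargo acts at the tangent point along the
free segment (the net wrench of an ideal frictionless cable around a
convex surface). This matters most for small cargos, where a straight
line from the far hemisphere to the filament would cut through the
sphere.

**Kinetics.** Per time step Δt, every motor attempts events in fixed
index order, with probabilities `p = 1 − exp(−rate·Δt)`:

* *attach* (detached motors): rate `k_on` whenever at least one site is
  within effective reach `L0`; the motor binds the site of smallest
  effective path length (ties to the lower index).
* *detach* (attached motors): rate `ε(F) = ε₀ exp(F/F_d)` with `F` the
  full cable tension.
* *step* (still-attached motors): rate
  `(v0/8 nm)·[ATP]/([ATP]+K_m)·max(0, 1 − (F∥/F_s)^w)`, an 8 nm advance
  toward the plus end. `F∥` is the component of the cable pull on the
  head opposing plus-end motion; assisting loads count as zero. No
  backward steps; the rate is zero at or beyond stall.

Loads are evaluated once per step on the pre-event configuration
("compute all forces, then ask each motor what it does"); the cargo is
then moved once using forces recomputed from the post-event
configuration. A transport run ends exactly when all motors are
simultaneously detached.

**Brownian dynamics.** The production integrator is the overdamped
limit with Stokes drag `α_T = 6πηR`, `α_R = 8πηR³` and
fluctuation–dissipation noise (`σ² = 2·kBT·Δt/α` per axis). Rotations
are applied as lab-frame rotation vectors composed onto the quaternion,
which is renormalized every step. Translational and rotational
viscosity multipliers are independent knobs because several experiments
mix them. Noise toggles (`trans_noise`, `rot_noise`) reproduce the
"no thermal" and "no rotational diffusion" control conditions;
deterministic drift from motor forces/torques remains active when only
the noise is disabled.

An explicit inertial (underdamped) Langevin integrator ships as a test
oracle only. For the cargo sizes simulated the momentum relaxation time
m/α_T is ≲ 10⁻⁷ s, orders of magnitude below any affordable Δt; the
test suite verifies that coarse-graining the inertial dynamics to Δt
reproduces the overdamped displacement distribution (KS test), the
terminal drift velocity F/α_T, and equipartition.

## Numerical treatment of the stiff cable

The cable is numerically stiff: the mechanical relaxation time `α_T/k`
(≈ 3 µs for R = 50 nm at water viscosity) is far below a usable Δt, so
explicit Euler–Maruyama is unstable whenever a cable is taut, and the
resulting tension spikes would bias detachment. Two measures fix this:

1. **Exponential (OU) update.** Each step, the taut cables' leading
   stiffness is linearized into 3×3 translational and rotational
   stiffness blocks (`Σ k ûûᵀ` and `Σ k (l×û)(l×û)ᵀ` over taut cables,
   with `û` the pull direction and `l` the lever arm). The update is
   the exact Ornstein–Uhlenbeck step per eigenmode: drift
   `F·(1−e^{−θ})/λ` and noise variance `(kBT/λ)(1−e^{−2θ})` with
   `θ = λΔt/α`. This is unconditionally stable, has the correct
   stationary variance in stiff modes, and reduces to Euler–Maruyama
   for slack (λ → 0) modes.
2. **Boundary substepping.** The cable law is non-smooth at
   `ext = L0`. Whenever any attached cable is within 16 nm of going
   taut, the cargo move is subdivided into substeps sized so that a
   single diffusion kick is ≲ 4 nm, preventing a full-size kick from
   jumping deep into the taut regime in one step.

The outer time step follows a stability rule unless set explicitly:
`Δt = min(10⁻⁴ s, bounds)` such that every per-step event probability
stays below 0.1, the translational kick σ_T stays below L0/10, and the
rotational surface kick σ_R·R below L0/5. This yields ≈ 1.4·10⁻⁵ s for
R = 50 nm and 10⁻⁴ s for large or viscous cargos. Run-length means at
Δt, Δt/4 and Δt/16 agree within Monte Carlo error.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| η | 10⁻⁹ pN·s/nm² | viscosity of water; multipliers scale it |
| kBT | 4.114 pN·nm | thermal energy (≈ 298 K; temperature is configurable) |
| L0 | 110 nm | motor rest (contour) length |
| k | 0.32 pN/nm | cable spring constant |
| k_on | 2 s⁻¹ | attachment rate while in reach |
| ε₀ | 1 s⁻¹ | unloaded detachment rate |
| F_d | 6 pN | detachment force scale |
| v0 | 800 nm/s | unloaded saturating velocity |
| F_s | 6 pN | stall force |
| w | 2 | force–velocity exponent |
| K_m | 50 µM | Michaelis constant for ATP |
| [ATP] | 2000 µM | saturating |
| step | 8 nm | step size |

ε₀ and v0 are chosen jointly so the unloaded single-motor run length
v0/ε₀ is 800 nm, the standard single-kinesin calibration point; F_s,
F_d, w and K_m are standard kinesin phenomenology. All are
configurable.

## Protocols and their conventions

* **Rotation-only binding time**: cargo tangent to the microtubule
  (optionally offset by `initial_gap_nm`), center frozen ("cannot
  diffuse away"), rotational noise on; time to first attachment.
  Means are reported over bound trials and flagged as censored when
  fewer than 95% bind within t_max.
* **Free binding fraction**: full diffusion from the resting position;
  success at first attachment, failure at t_max or when the center's
  distance to the nearest microtubule axis exceeds the escape radius
  (50 motor lengths = 5500 nm by convention).
* **Slab**: as above inside ±1 µm z-walls; wall contact resets z so
  the sphere just touches the wall. The infinite microtubule array
  uses periodic x-wrapping (applied only while no motor is bound).
* **Transport runs**: the cargo is rotated so its best-positioned
  motor sits at the South Pole; every motor then takes its initial
  opportunity to attach, so all motors within reach of a free site
  start bound (one head per site). Dynamics run until all motors
  detach. Run length is the net displacement of the cargo center
  along the plus direction. Starting fully loaded matters: from a
  single bound motor, the lower tail of the run-length distribution
  is set by early cascade failure rather than by transport. Trials
  still bound at t_max are censored and reported as such.
* **Engaged census**: transport runs that accumulate the time-weighted
  distribution of the number of attached motors. Census runs start
  from a single bound motor (the census measures recruitment building
  up to and fluctuating about its steady state) and are capped at a
  few seconds of simulated time per run.

Paired comparisons across conditions reuse the same per-trial seed
sequence to maximize statistical power at small trial counts.

**Analysis conventions.** The 20th-percentile run length (the distance
80% of cargos exceed, "L80") uses the inverted-ECDF order statistic —
the smallest sample value with ECDF ≥ 0.2 — since "percentile" is
otherwise convention-dependent. Windowed velocities divide the axial
displacement over non-overlapping windows of τ (1–10 ms) by τ. The
Poisson fit to the engaged census fixes λ at the sample mean (the only
adjustable parameter) and reports a chi-square statistic over occupied
bins. Run-length means carry bootstrap 95% CIs (1000 resamples)
because the sampling error of skewed run-length distributions is easy
to underestimate.

## Problem sizes

The shipped test-suite and acceptance protocols run at desk scale:
200–2000 trials per condition (binding-fraction curves that were
originally drawn from 6000 trials use 200–500), and census/transport
runs are capped at 4–60 s of simulated time per trial depending on the
protocol. Percentile estimates are placed well below the caps so
censoring cannot move them; censored counts are always reported.

## Known limitations

* Motor anchors are fixed on the cargo surface; membrane-fluid
  (diffusing) anchors are out of scope.
* Single-head stepping kinetics: no hand-over-hand gating, ADP/Pi
  substates, or backward slips.
* No hydrodynamic wall coupling or anisotropic drag; the slab walls
  act only through excluded volume.
* Motor–motor and motor–microtubule collisions are ignored; excluded
  volume acts between the cargo sphere and the microtubule cylinders /
  slab walls, and on the cable path around the cargo itself.
* The rotational OU linearization keeps only the leading (longitudinal)
  cable stiffness; transverse and translation–rotation coupling terms
  are dropped. The substep bounds keep the resulting discretization
  error below sampling error (checked by Δt refinement).
* The synthetic experiments model in-vitro-like conditions (uniform
  viscosity, straight rigid microtubules, no obstacles); passing tests
  demonstrates the model's internal consistency and its agreement with
  the published simulation behavior, not agreement with any particular
  wet experiment.
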