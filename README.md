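# motorcargo

A three-dimensional Monte Carlo / Brownian-dynamics simulator of
vesicular transport: a spherical cargo carrying elastic motor proteins
(kinesin-like) that bind to, step along, and detach from cylindrical
microtubules, while the cargo itself undergoes translational and
rotational thermal diffusion.

The package is for quantitatively studying how the *cargo* — its size,
the viscosity of its environment, and the arrangement of motors on its
surface — changes motor function: the effective on-rate of a
cargo-bound motor, the fraction of cargos that bind before diffusing
away, the number of simultaneously engaged motors, and the run length
and velocity of transport. Typical users are biophysicists modelling
multi-motor transport or benchmarking analytic approximations (e.g.
Poisson estimates of engaged-motor numbers) against an explicit 3D
simulation.

## Model in brief

The cargo is a rigid sphere (radius `R`) with state `(r, q)` — center
position and orientation quaternion — obeying overdamped Langevin
dynamics with Stokes drag `α_T = 6πηR`, `α_R = 8πηR³`:

    r(t+Δt) = r(t) + (F/α_T)Δt + √(2·kBT·Δt/α_T)·N(0,1)³

and the analogous rotation-vector update for `q`. Each motor is a
cable ("bungee") spring anchored at a fixed point on the sphere:
tension `k(ext − L0)` when its cargo-avoiding path to the bound head
exceeds the rest length `L0 = 110 nm` (`k = 0.32 pN/nm`), zero force
when slack. Per time step each motor attaches at rate `k_on = 2 s⁻¹`
when a binding site (8 nm lattice on a 25 nm-diameter cylinder) is
within straight-stalk reach, detaches at rate `ε₀·exp(F/F_d)`, and
steps 8 nm toward the plus end at rate
`(v0/8)·[ATP]/([ATP]+K_m)·(1 − (F∥/F_s)²)` — Michaelis–Menten ATP
kinetics with a stall at `F_s`. A run ends when every motor is
detached; the run length is the net axial displacement.

The stiff cable dynamics are integrated with an exponential
(Ornstein–Uhlenbeck) update on the linearized stiffness, which is
stable and has the exact stationary variance in the taut modes; see
`docs/methods.md` for the numerics, parameter defaults and
limitations.

## Worked example

Time-averaged number of engaged motors for 5 motors placed uniformly
at random on a 500 nm-diameter cargo, at the viscosity of water:

```python
from motorcargo import WorldConfig, engaged_census

cfg = WorldConfig(protocol="census", R=250.0, n_motors=5,
                  placement="uniform", t_max=4.0)
trials, hist, summary = engaged_census(cfg, seed=11, n_trials=120)
print(round(summary["mean_engaged"], 2))
```

This prints `1.29`: although 5 motors are present, on average only
~1.3 can simultaneously reach the microtubule from a cargo this large
— the geometric origin of the claim that large cargos need motor
clustering. The same census on a 100 nm-diameter cargo
(`R=50`) prints `2.45`: roughly half the motors are engaged, because
the 110 nm motors out-reach the cargo radius.

The same protocols are scriptable from the shell:

```sh
motorcargo fixtures --out configs/           # canonical experiment configs
motorcargo census --config configs/table1_census.toml --seed 11 --out out/
```

Each run writes a per-trial CSV and a summary JSON stamped with the
config hash and seed; rerunning with the same seed reproduces the
files byte-for-byte.

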