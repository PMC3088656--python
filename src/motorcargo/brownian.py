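"""Overdamped Brownian-dynamics updates for a rigid sphere.

Production integrator: first-order Euler–Maruyama in the overdamped
limit.  Translation:

    r(t+Δt) = r(t) + (F/α_T) Δt + σ_T N(0,1)³,   σ_T = sqrt(2 kBT Δt / α_T)

Rotation is the analogous update on a rotation vector
θ = (T/α_R) Δt + σ_R N(0,1)³ applied as a lab-frame rotation composed
with the orientation quaternion.  Drag follows Stokes' law for a sphere:
α_T = 6πηR, α_R = 8πηR³.  The noise amplitudes come from the
fluctuation–dissipation relation, so a free cargo obeys the Einstein
relations D_T = kBT/α_T and D_R = kBT/α_R.

An explicit inertial (underdamped) integrator is included purely as a
validation oracle: at these scales the momentum relaxation time m/α_T
is far below any usable Δt, and the tests verify that coarse-graining
the inertial dynamics reproduces the overdamped update statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CargoState, Environment, quat_from_rotvec, quat_multiply, quat_normalize


@dataclass(frozen=True)
class DragCoefficients:
    alpha_T: float  # pN·s/nm
    alpha_R: float  # pN·s·nm


def drag(R: float, eta: float) -> DragCoefficients:
    """Stokes drag coefficients of a sphere of radius R (nm) in a fluid
    of viscosity eta (pN·s/nm²)."""
    if R <= 0 or eta <= 0:
        raise ValueError("radius and viscosity must be positive")
    return DragCoefficients(alpha_T=6.0 * np.pi * eta * R,
                            alpha_R=8.0 * np.pi * eta * R**3)


def step_translation(
    cargo: CargoState,
    F_total: np.ndarray,
    dt: float,
    env: Environment,
    rng: np.random.Generator,
    noise_on: bool = True,
    alpha_T: float | None = None,
) -> np.ndarray:
    """One overdamped translational update; returns the new position."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if alpha_T is None:
        alpha_T = drag(cargo.R, env.eta).alpha_T
    r = cargo.r + np.asarray(F_total, dtype=float) / alpha_T * dt
    if noise_on:
        sigma = np.sqrt(2.0 * env.kBT * dt / alpha_T)
        r = r + sigma * rng.standard_normal(3)
    return r


def step_rotation(
    cargo: CargoState,
    T_total: np.ndarray,
    dt: float,
    env: Environment,
    rng: np.random.Generator,
    noise_on: bool = True,
    alpha_R: float | None = None,
) -> np.ndarray:
    """One overdamped rotational update; returns the new unit quaternion."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if alpha_R is None:
        alpha_R = drag(cargo.R, env.eta).alpha_R
    theta = np.asarray(T_total, dtype=float) / alpha_R * dt
    if noise_on:
        sigma = np.sqrt(2.0 * env.kBT * dt / alpha_R)
        theta = theta + sigma * rng.standard_normal(3)
    dq = quat_from_rotvec(theta)
    return quat_normalize(quat_multiply(dq, cargo.q))


def inertial_translation_oracle(
    m: float,
    alpha_T: float,
    kBT: float,
    F: np.ndarray,
    dt_small: float,
    n_inner: int,
    n_samples: int,
    rng: np.random.Generator,
    noise_on: bool = True,
) -> np.ndarray:
    """Underdamped Langevin displacements, coarse-grained over n_inner
    sub-steps of size dt_small.

    Integrates  m dv = (F − α_T v) dt + sqrt(2 kBT α_T) dW  per axis with
    explicit Euler–Maruyama (requires dt_small ≪ m/α_T for stability),
    starting each sample from the Maxwell velocity distribution.
    Returns an (n_samples, 3) array of displacements over the coarse
    interval n_inner*dt_small — the oracle against which the one-shot
    overdamped update is validated.
    """
    tau = m / alpha_T
    if dt_small > 0.1 * tau:
        raise ValueError("dt_small too large for the inertial integrator")
    F = np.asarray(F, dtype=float)
    v = rng.standard_normal((n_samples, 3)) * np.sqrt(kBT / m) if noise_on else np.zeros((n_samples, 3))
    x = np.zeros((n_samples, 3))
    amp = np.sqrt(2.0 * kBT * alpha_T * dt_small) / m
    for _ in range(n_inner):
        x += v * dt_small
        dv = (F - alpha_T * v) * (dt_small / m)
        if noise_on:
            dv = dv + amp * rng.standard_normal((n_samples, 3))
        v += dv
    return x
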