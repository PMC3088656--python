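"""Sampling motor anchor points on the cargo surface.

Anchors are unit vectors in the cargo body frame.  At t = 0 the body
frame coincides with the lab frame, so the South Pole (0, 0, −1) is the
point facing the microtubule.  Three placement modes:

* ``uniform`` — uniform over the whole sphere (cluster angle 180°);
* ``cone(phi)`` — uniform over the spherical cap of half-angle phi
  centred on the South Pole (phi = 0 → single point at the pole,
  phi = 90° → lower hemisphere, phi = 180° → whole sphere);
* ``point`` — all N motors share one anchor, sampled uniformly at
  random on the sphere (a "clustered at one point" cargo).
"""

from __future__ import annotations

import numpy as np

MODES = ("uniform", "cone", "point")


def sample_uniform_sphere(rng: np.random.Generator) -> np.ndarray:
    return sample_cone(np.pi, rng)


def sample_cone(phi: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform point on the spherical cap of half-angle phi about the
    South Pole.  By Archimedes' theorem, uniform area means cos(theta)
    uniform on [cos(phi), 1], measuring theta from the cap centre."""
    if not 0.0 <= phi <= np.pi:
        raise ValueError("cone half-angle must lie in [0, pi]")
    # polar angle from the -z axis
    cos_t = 1.0 - rng.random() * (1.0 - np.cos(phi))
    sin_t = np.sqrt(max(1.0 - cos_t * cos_t, 0.0))
    az = rng.random() * 2.0 * np.pi
    return np.array([sin_t * np.cos(az), sin_t * np.sin(az), -cos_t])


def place_motors(
    N: int,
    mode: str,
    rng: np.random.Generator,
    phi: float = np.pi,
) -> np.ndarray:
    """Sample N anchor unit vectors; returns an (N, 3) array."""
    if N < 1:
        raise ValueError("need at least one motor")
    if mode not in MODES:
        raise ValueError(f"unknown placement mode {mode!r}")
    if mode == "point":
        a = sample_uniform_sphere(rng)
        return np.tile(a, (N, 1))
    if mode == "uniform":
        phi = np.pi
    return np.vstack([sample_cone(phi, rng) for _ in range(N)])


def surface_density(N: int, R: float) -> float:
    """Motor surface density N / (4πR²), in nm⁻²; defined on the whole
    sphere regardless of placement mode."""
    return N / (4.0 * np.pi * R * R)
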