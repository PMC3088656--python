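"""Motor linkage geometry, cable force law, force/torque assembly,
and excluded-volume resolution.

The motor linkage is a cable (bungee) spring: tension
``k_spring * (extension - L0)`` when stretched beyond the rest length,
zero when slack.  An attached motor's head is point-located at the
surface point of its binding site on the microtubule cylinder, taken in
the half-plane containing the anchor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

from .core import (
    CargoState,
    Environment,
    MicrotubuleLattice,
    MotorState,
    anchor_position,
)


@dataclass(frozen=True)
class LinkageForce:
    tension: float        # pN, >= 0
    direction: np.ndarray  # unit vector anchor -> head
    extension: float       # nm


def site_position(mt: MicrotubuleLattice, i: int, anchor: np.ndarray) -> np.ndarray:
    """Surface point of binding site i nearest to the anchor.

    The site's axial station is ``origin + i*spacing*axis``; the radial
    placement is on the cylinder surface in the half-plane containing
    the anchor.
    """
    anchor = np.asarray(anchor, dtype=float)
    axial = mt.site_axis_point(i)
    d = anchor - axial
    d_perp = d - np.dot(d, mt.axis) * mt.axis
    n = np.linalg.norm(d_perp)
    if n < 1e-12:
        # anchor on the axis: any azimuth; pick +z deterministically
        ref = np.array([0.0, 0.0, 1.0])
        d_perp = ref - np.dot(ref, mt.axis) * mt.axis
        n = np.linalg.norm(d_perp)
    return axial + mt.radius_mt * d_perp / n


def effective_cable_length(anchor: np.ndarray, center: np.ndarray, R: float,
                           site: np.ndarray) -> float:
    """Shortest cable path from an anchor on the cargo sphere to a site,
    not passing through the cargo.

    Direct distance when the site lies on or above the tangent plane at
    the anchor; otherwise a geodesic arc to the tangent point plus the
    straight tangent segment.
    """
    anchor = np.asarray(anchor, dtype=float)
    center = np.asarray(center, dtype=float)
    site = np.asarray(site, dtype=float)
    v = site - anchor
    w = anchor - center
    if float(np.dot(v, w)) >= 0.0:
        return float(np.linalg.norm(v))
    e = site - center
    dc = float(np.linalg.norm(e))
    cospsi = np.clip(np.dot(w, e) / (R * dc), -1.0, 1.0)
    psi = np.arccos(cospsi)
    if dc <= R + 1e-6:
        return float(R * psi)
    return float(np.sqrt(dc * dc - R * R) + R * (psi - np.arccos(R / dc)))


def linkage(anchor: np.ndarray, head: np.ndarray, k: float, L0: float) -> LinkageForce:
    """Cable force of the anchor→head linkage."""
    anchor = np.asarray(anchor, dtype=float)
    head = np.asarray(head, dtype=float)
    d = head - anchor
    ext = float(np.linalg.norm(d))
    if ext < 1e-12:
        raise ValueError("anchor and head coincide; linkage direction undefined")
    direction = d / ext
    tension = k * (ext - L0) if ext > L0 else 0.0
    return LinkageForce(tension=tension, direction=direction, extension=ext)


def motor_head_position(
    cargo: CargoState, motor: MotorState, mt: MicrotubuleLattice
) -> np.ndarray:
    if not motor.attached or motor.site_index is None:
        raise ValueError("motor is not attached")
    return site_position(mt, motor.site_index, anchor_position(cargo, motor))


def assemble_force_torque(
    cargo: CargoState,
    motors: Iterable[MotorState],
    env: Environment,
    mt: Optional[MicrotubuleLattice] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Total force (pN) and torque about the cargo center (pN·nm).

    F = F_ext + sum of attached-motor cable tensions; each tension acts
    at the motor's anchor point, giving torque (anchor − r) × f.
    Detached motors contribute nothing.
    """
    F = env.F_ext.astype(float).copy()
    T = np.zeros(3)
    for m in motors:
        if not m.attached:
            continue
        if mt is None:
            raise ValueError("attached motors require a microtubule")
        a = anchor_position(cargo, m)
        head = site_position(mt, m.site_index, a)
        lf = linkage(a, head, m.k_spring, m.L0)
        if lf.tension > 0.0:
            f = lf.tension * lf.direction
            F += f
            T += np.cross(a - cargo.r, f)
    return F, T


def resolve_overlap(
    cargo: CargoState,
    mts: Sequence[MicrotubuleLattice],
    slab_z: Optional[Tuple[float, float]] = None,
) -> np.ndarray:
    """Project the cargo center out of any penetrated cylinder or wall.

    If the center-to-axis distance of any microtubule is below
    R + radius_mt the center is pushed radially outward to exact
    contact; slab violations reset z so the sphere just touches the
    wall.  Idempotent.
    """
    r = cargo.r.astype(float).copy()
    for mt in mts:
        d = r - mt.origin
        d_perp = d - np.dot(d, mt.axis) * mt.axis
        dist = np.linalg.norm(d_perp)
        rmin = cargo.R + mt.radius_mt
        if dist < rmin:
            axial = mt.origin + np.dot(d, mt.axis) * mt.axis
            if dist < 1e-9:
                # center on the axis: push straight up
                up = np.array([0.0, 0.0, 1.0])
                d_perp = up - np.dot(up, mt.axis) * mt.axis
                d_perp /= np.linalg.norm(d_perp)
                r = axial + rmin * d_perp
            else:
                r = axial + d_perp * (rmin / dist)
    if slab_z is not None:
        zmin, zmax = slab_z
        if r[2] + cargo.R > zmax:
            r[2] = zmax - cargo.R
        if r[2] - cargo.R < zmin:
            r[2] = zmin + cargo.R
    return r
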