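"""Domain types, unit conventions, and rigid-body kinematics.

Unit convention, used everywhere in the package:

* length    — nanometres (nm)
* time      — seconds (s)
* force     — piconewtons (pN)
* energy    — pN·nm  (kBT ≈ 4.114 pN·nm at 298 K)
* viscosity — pN·s/nm² (water ≈ 1e-9 pN·s/nm²)
* angles    — radians

Frames: the *lab frame* has the microtubule axis along +y, z vertical
(pointing up, away from the filament) and x lateral.  The *body frame* is
fixed to the cargo; a motor anchor is a unit vector in the body frame and
the anchor point sits at ``R * anchor_body`` on the sphere surface.
Orientation is stored as a unit quaternion (w, x, y, z) mapping body to
lab coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: thermal energy at ~298 K, pN·nm
KBT_ROOM = 4.114
#: dynamic viscosity of water, pN·s/nm²
ETA_WATER = 1.0e-9

_QUAT_TOL = 1e-9


class InvalidStateError(ValueError):
    """Raised when a rigid-body state violates its invariants."""


# ---------------------------------------------------------------------------
# quaternion utilities (scalar-first convention, body -> lab)
# ---------------------------------------------------------------------------

def quat_identity() -> np.ndarray:
    return np.array([1.0, 0.0, 0.0, 0.0])


def quat_normalize(q: np.ndarray) -> np.ndarray:
    n = np.sqrt(np.dot(q, q))
    if n == 0.0:
        raise InvalidStateError("zero quaternion")
    return q / n


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a*b (apply b first, then a)."""
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ]
    )


def quat_from_rotvec(v: np.ndarray) -> np.ndarray:
    """Quaternion for a rotation by |v| radians about v/|v|."""
    v = np.asarray(v, dtype=float)
    theta = np.sqrt(np.dot(v, v))
    if theta < 1e-300:
        return quat_identity()
    half = 0.5 * theta
    s = np.sin(half) / theta
    return np.array([np.cos(half), v[0] * s, v[1] * s, v[2] * s])


def quat_rotate(q: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Rotate vector p (body frame) into the lab frame."""
    w, x, y, z = q
    # R(q) @ p, expanded
    px, py, pz = p
    tx = 2.0 * (y * pz - z * py)
    ty = 2.0 * (z * px - x * pz)
    tz = 2.0 * (x * py - y * px)
    return np.array(
        [
            px + w * tx + (y * tz - z * ty),
            py + w * ty + (z * tx - x * tz),
            pz + w * tz + (x * ty - y * tx),
        ]
    )


def quat_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Smallest rotation taking unit vector u onto unit vector v."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    c = float(np.dot(u, v))
    if c < -1.0 + 1e-12:
        # antipodal: rotate pi about any axis perpendicular to u
        axis = np.cross(u, np.array([1.0, 0.0, 0.0]))
        if np.dot(axis, axis) < 1e-12:
            axis = np.cross(u, np.array([0.0, 1.0, 0.0]))
        axis /= np.linalg.norm(axis)
        return np.array([0.0, axis[0], axis[1], axis[2]])
    axis = np.cross(u, v)
    q = np.array([1.0 + c, axis[0], axis[1], axis[2]])
    return quat_normalize(q)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Environment:
    """Solvent and external-load description.

    ``eta`` is the baseline viscosity; protocols may scale translational
    and rotational drag independently (see WorldConfig multipliers).
    """

    eta: float = ETA_WATER          # pN·s/nm²
    kBT: float = KBT_ROOM           # pN·nm
    F_ext: np.ndarray = field(default_factory=lambda: np.zeros(3))  # pN
    atp: float = 2000.0             # µM (saturating for kinesin)

    def __post_init__(self) -> None:
        self.F_ext = np.asarray(self.F_ext, dtype=float)
        if self.eta <= 0:
            raise ValueError("viscosity must be positive")
        if self.kBT <= 0:
            raise ValueError("kBT must be positive")
        if self.atp < 0:
            raise ValueError("ATP concentration must be nonnegative")


@dataclass
class CargoState:
    """Rigid spherical cargo: center position, orientation, radius.

    ``mass_density`` (kg/m³) is used only by the inertial validation
    integrator; the production overdamped dynamics never touch it.
    """

    r: np.ndarray = field(default_factory=lambda: np.zeros(3))  # nm, lab
    q: np.ndarray = field(default_factory=quat_identity)        # body->lab
    R: float = 250.0                                            # nm
    mass_density: float = 1000.0                                # kg/m³

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.R <= 0:
            raise ValueError("cargo radius must be positive")
        self.check_quaternion()

    def check_quaternion(self) -> None:
        if abs(np.linalg.norm(self.q) - 1.0) > 1e-6:
            raise InvalidStateError("orientation quaternion is not unit length")

    @property
    def mass(self) -> float:
        """Cargo mass in pN·s²/nm (1 kg = 1e3 pN·s²/nm)."""
        vol_m3 = (4.0 / 3.0) * np.pi * (self.R * 1e-9) ** 3
        return self.mass_density * vol_m3 * 1e3

    @property
    def moment_of_inertia(self) -> float:
        """Solid-sphere moment of inertia (2/5) m R², pN·s²·nm."""
        return 0.4 * self.mass * self.R**2


@dataclass
class MotorState:
    """A single motor: anchor fixed in the cargo body frame plus its
    mechanical (cable spring) and kinetic (attach/detach/step) parameters.

    The linkage behaves as a cable: tension k_spring·(ext − L0) when
    stretched beyond the rest length L0, zero force when shorter.
    """

    anchor_body: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, -1.0]))
    attached: bool = False
    site_index: Optional[int] = None
    L0: float = 110.0        # nm rest length
    k_spring: float = 0.32   # pN/nm
    k_on: float = 2.0        # s⁻¹
    eps0: float = 1.0        # s⁻¹ unloaded detachment rate
    F_d: float = 6.0         # pN detachment force scale
    v0: float = 800.0        # nm/s unloaded saturating velocity
    F_s: float = 6.0         # pN stall force
    K_m: float = 50.0        # µM Michaelis constant
    step: float = 8.0        # nm

    def __post_init__(self) -> None:
        self.anchor_body = np.asarray(self.anchor_body, dtype=float)
        n = np.linalg.norm(self.anchor_body)
        if abs(n - 1.0) > 1e-9:
            if n == 0:
                raise ValueError("anchor_body must be a unit vector")
            self.anchor_body = self.anchor_body / n
        if self.L0 <= 0:
            raise ValueError("rest length must be positive")
        if self.k_spring < 0:
            raise ValueError("spring constant must be nonnegative")
        if self.attached != (self.site_index is not None):
            raise InvalidStateError("attached flag inconsistent with site_index")


@dataclass
class MicrotubuleLattice:
    """Cylindrical microtubule with binding sites every 8 nm along its axis.

    Site ``i`` lies at ``origin + i*site_spacing*axis`` on the axis;
    attachment geometry projects it onto the cylinder surface in the
    half-plane of the approaching motor anchor (see mechanics).
    """

    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    radius_mt: float = 12.5      # nm (25 nm diameter)
    site_spacing: float = 8.0    # nm
    plus_dir: int = 1            # +1 or -1 along axis

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        self.axis = self.axis / np.linalg.norm(self.axis)
        if self.radius_mt <= 0:
            raise ValueError("microtubule radius must be positive")
        if self.plus_dir not in (-1, 1):
            raise ValueError("plus_dir must be +1 or -1")

    def site_axis_point(self, i: int) -> np.ndarray:
        return self.origin + i * self.site_spacing * self.axis


# ---------------------------------------------------------------------------
# rigid-body transforms
# ---------------------------------------------------------------------------

def body_to_lab(cargo: CargoState, p_body: np.ndarray) -> np.ndarray:
    """Map a body-frame point to the lab frame: r + R(q) @ p_body."""
    if abs(np.linalg.norm(cargo.q) - 1.0) > 1e-6:
        raise InvalidStateError("orientation quaternion is not unit length")
    return cargo.r + quat_rotate(cargo.q, np.asarray(p_body, dtype=float))


def anchor_position(cargo: CargoState, motor: MotorState) -> np.ndarray:
    """Lab-frame position of a motor's anchor point on the sphere surface."""
    return body_to_lab(cargo, cargo.R * motor.anchor_body)
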