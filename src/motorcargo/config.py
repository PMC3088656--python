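"""World configuration: schema, TOML loading/validation, time-step
selection, and canonical experiment fixtures.

A configuration file is a TOML document with the sections

    [protocol]     name, t_max, n_trials, seed, escape_radius_nm,
                   initial_gap_nm
    [cargo]        radius_nm, mass_density
    [environment]  eta, kBT, visc_mult_trans, visc_mult_rot, atp_uM, F_ext
    [motors]       n, placement, phi_degrees, L0_nm, k_spring, k_on,
                   eps0, F_d, F_s, w, K_m_uM, v0, step_nm
    [microtubule]  radius_nm, site_spacing_nm, plus_dir, x_spacing_nm,
                   periodic
    [simulation]   dt, dt_cap, slab_zmin, slab_zmax, trans_noise,
                   rot_noise, record_stride_s

Unknown keys are rejected.  Every field has a documented default, so a
minimal file only states what differs from the defaults.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from .brownian import drag
from .core import ETA_WATER, KBT_ROOM

PROTOCOLS = ("bind_time", "bind_fraction", "slab", "run", "census")


@dataclass
class WorldConfig:
    """Complete description of one in-silico experiment."""

    # protocol
    protocol: str = "run"
    t_max: float = 60.0              # s
    n_trials: int = 200
    seed: int = 0
    escape_radius: Optional[float] = None   # nm, center-to-MT-axis
    initial_gap_nm: float = 0.0             # gap between sphere bottom and MT top

    # cargo
    R: float = 250.0                 # nm
    mass_density: float = 1000.0     # kg/m³, inertial oracle only

    # environment
    eta: float = ETA_WATER           # pN·s/nm² (baseline, 1x = water)
    kBT: float = KBT_ROOM            # pN·nm
    visc_mult_trans: float = 1.0
    visc_mult_rot: float = 1.0
    atp: float = 2000.0              # µM
    F_ext: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    # motors
    n_motors: int = 1
    placement: str = "uniform"       # uniform | cone | point
    phi_degrees: float = 180.0
    L0: float = 110.0                # nm
    k_spring: float = 0.32           # pN/nm
    k_on: float = 2.0                # s⁻¹
    eps0: float = 1.0                # s⁻¹
    F_d: float = 6.0                 # pN
    F_s: float = 6.0                 # pN
    w: float = 2.0                   # force–velocity exponent
    K_m: float = 50.0                # µM
    v0: float = 800.0                # nm/s
    step_nm: float = 8.0

    # microtubule geometry
    mt_radius: float = 12.5          # nm
    site_spacing: float = 8.0        # nm
    plus_dir: int = 1
    x_mt: Optional[float] = None     # spacing of the periodic MT array, nm
    periodic: bool = False
    slab_z: Optional[Tuple[float, float]] = None

    # integration
    dt: Optional[float] = None       # None → stability rule
    dt_cap: float = 1.0e-4           # s
    trans_noise: bool = True
    rot_noise: bool = True
    record_stride_s: Optional[float] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.R <= 0 or self.eta <= 0 or self.kBT <= 0:
            raise ValueError("R, eta and kBT must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.n_motors < 1:
            raise ValueError("need at least one motor")
        if not 0.0 <= self.phi_degrees <= 180.0:
            raise ValueError("cluster angle must lie between 0 and 180 degrees")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.periodic and not (self.x_mt and self.x_mt > 0):
            raise ValueError("periodic geometry requires a positive x_mt spacing")
        if self.plus_dir not in (-1, 1):
            raise ValueError("plus_dir must be +1 or -1")
        if self.placement not in ("uniform", "cone", "point"):
            raise ValueError(f"unknown placement mode {self.placement!r}")

    # -- derived quantities -------------------------------------------------

    @property
    def alpha_T(self) -> float:
        return drag(self.R, self.eta * self.visc_mult_trans).alpha_T

    @property
    def alpha_R(self) -> float:
        return drag(self.R, self.eta * self.visc_mult_rot).alpha_R

    @property
    def phi(self) -> float:
        return np.deg2rad(self.phi_degrees)

    def effective_dt(self) -> float:
        """Time step from the stability rule, unless set explicitly.

        Bounds: every per-step event probability < 0.1; translational
        noise kick σ_T < L0/10; rotational surface kick σ_R·R < L0/5.
        """
        if self.dt is not None:
            return self.dt
        mm = self.atp / (self.atp + self.K_m) if self.atp > 0 else 0.0
        rate_max = max(self.k_on, (self.v0 / self.step_nm) * mm,
                       self.eps0 * np.e**2)
        bounds = [self.dt_cap, 0.1 / rate_max]
        bounds.append(self.L0**2 * self.alpha_T / (200.0 * self.kBT))
        bounds.append(self.L0**2 * self.alpha_R / (50.0 * self.kBT * self.R**2))
        return float(min(bounds))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# TOML schema
# ---------------------------------------------------------------------------

_SCHEMA = {
    "protocol": {
        "name": "protocol",
        "t_max": "t_max",
        "n_trials": "n_trials",
        "seed": "seed",
        "escape_radius_nm": "escape_radius",
        "initial_gap_nm": "initial_gap_nm",
    },
    "cargo": {
        "radius_nm": "R",
        "mass_density": "mass_density",
    },
    "environment": {
        "eta": "eta",
        "kBT": "kBT",
        "visc_mult_trans": "visc_mult_trans",
        "visc_mult_rot": "visc_mult_rot",
        "atp_uM": "atp",
        "F_ext": "F_ext",
    },
    "motors": {
        "n": "n_motors",
        "placement": "placement",
        "phi_degrees": "phi_degrees",
        "L0_nm": "L0",
        "k_spring": "k_spring",
        "k_on": "k_on",
        "eps0": "eps0",
        "F_d": "F_d",
        "F_s": "F_s",
        "w": "w",
        "K_m_uM": "K_m",
        "v0": "v0",
        "step_nm": "step_nm",
    },
    "microtubule": {
        "radius_nm": "mt_radius",
        "site_spacing_nm": "site_spacing",
        "plus_dir": "plus_dir",
        "x_spacing_nm": "x_mt",
        "periodic": "periodic",
    },
    "simulation": {
        "dt": "dt",
        "dt_cap": "dt_cap",
        "slab_zmin": "slab_zmin",
        "slab_zmax": "slab_zmax",
        "trans_noise": "trans_noise",
        "rot_noise": "rot_noise",
        "record_stride_s": "record_stride_s",
    },
}


def load_config(path: str | Path) -> WorldConfig:
    """Parse and validate a TOML world configuration."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    kwargs: dict = {}
    slab = {}
    for section, entries in doc.items():
        if section not in _SCHEMA:
            raise ValueError(f"unknown config section [{section}]")
        if not isinstance(entries, dict):
            raise ValueError(f"[{section}] must be a table")
        for key, value in entries.items():
            if key not in _SCHEMA[section]:
                raise ValueError(f"unknown key {key!r} in section [{section}]")
            target = _SCHEMA[section][key]
            if target in ("slab_zmin", "slab_zmax"):
                slab[target] = float(value)
            elif target == "F_ext":
                kwargs[target] = tuple(float(v) for v in value)
            else:
                kwargs[target] = value
    if slab:
        if set(slab) != {"slab_zmin", "slab_zmax"}:
            raise ValueError("slab requires both slab_zmin and slab_zmax")
        kwargs["slab_z"] = (slab["slab_zmin"], slab["slab_zmax"])
    return WorldConfig(**kwargs)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {v!r}")


def dump_config(cfg: WorldConfig, path: str | Path) -> None:
    """Write a WorldConfig back out as TOML (full, explicit form)."""
    inv = {sec: {k: t for k, t in entries.items()} for sec, entries in _SCHEMA.items()}
    values = asdict(cfg)
    lines = []
    for section, entries in inv.items():
        body = []
        for key, target in entries.items():
            if target in ("slab_zmin", "slab_zmax"):
                if values["slab_z"] is not None:
                    idx = 0 if target == "slab_zmin" else 1
                    body.append(f"{key} = {_toml_value(values['slab_z'][idx])}")
                continue
            v = values[target]
            if v is None:
                continue
            body.append(f"{key} = {_toml_value(v)}")
        if body:
            lines.append(f"[{section}]")
            lines.extend(body)
            lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# canonical experiment fixtures
# ---------------------------------------------------------------------------

def fixture_configs() -> dict[str, WorldConfig]:
    """Named configurations for the simulator's standard experiments.

    Each encodes one published measurement condition; *_scaled variants
    reduce trial counts to desk scale.
    """
    fx: dict[str, WorldConfig] = {}
    fx["fig3_bindtime"] = WorldConfig(
        protocol="bind_time", R=250.0, n_motors=1, placement="uniform",
        t_max=60.0, n_trials=1000,
    )
    fx["fig4_bindfraction"] = WorldConfig(
        protocol="bind_fraction", R=250.0, n_motors=1, placement="uniform",
        t_max=30.0, escape_radius=5500.0, n_trials=6000,
    )
    fx["fig4_bindfraction_scaled"] = WorldConfig(
        protocol="bind_fraction", R=250.0, n_motors=1, placement="uniform",
        t_max=30.0, escape_radius=5500.0, n_trials=500,
    )
    fx["fig8_1overN"] = WorldConfig(
        protocol="bind_time", R=100.0, n_motors=4, placement="uniform",
        initial_gap_nm=50.0, t_max=60.0, n_trials=500,
    )
    fx["fig9_lengthscan"] = WorldConfig(
        protocol="bind_time", R=100.0, n_motors=1, placement="uniform",
        L0=110.0, t_max=120.0, n_trials=200,
    )
    fx["fig10_slab"] = WorldConfig(
        protocol="slab", R=250.0, n_motors=1, placement="uniform",
        visc_mult_trans=10.0, visc_mult_rot=10.0,
        x_mt=800.0, periodic=True, slab_z=(-1000.0, 1000.0),
        t_max=60.0, n_trials=1000,
    )
    fx["table1_census"] = WorldConfig(
        protocol="census", R=50.0, n_motors=5, placement="uniform",
        t_max=5.0, n_trials=200,
    )
    fx["fig13_l80"] = WorldConfig(
        protocol="run", R=250.0, n_motors=5, placement="cone", phi_degrees=0.0,
        visc_mult_trans=2.0, visc_mult_rot=2.0, t_max=60.0, n_trials=200,
    )
    fx["fig18_clusterN"] = WorldConfig(
        protocol="run", R=250.0, n_motors=5, placement="cone", phi_degrees=0.0,
        t_max=60.0, n_trials=500,
    )
    fx["fig22_cluster_vs_random"] = WorldConfig(
        protocol="bind_fraction", R=250.0, n_motors=4, placement="point",
        t_max=60.0, escape_radius=5500.0, n_trials=500,
    )
    fx["porpoise_nonoise"] = WorldConfig(
        protocol="run", R=500.0, n_motors=1, placement="cone", phi_degrees=0.0,
        trans_noise=False, rot_noise=False, t_max=2.0, n_trials=1,
        dt=1.0e-5, record_stride_s=1.0e-4,
    )
    return fx


def make_fixtures(out_dir: str | Path) -> list[Path]:
    """Write every canonical fixture as TOML; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, cfg in fixture_configs().items():
        p = out / f"{name}.toml"
        dump_config(cfg, p)
        paths.append(p)
    return paths
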