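"""In-silico experimental protocols.

Each protocol is a reproducible trial generator: given a WorldConfig and
a seed it spawns one independent RNG stream per trial (so trial sets are
reproducible and order-independent), runs the compiled trial kernel, and
returns a per-trial pandas DataFrame plus a summary dict.

Protocols
---------
``binding_time_rotation_only``
    Cargo resting on the microtubule with translation frozen; rotational
    diffusion (plus any motor torque) on; measures time to first
    attachment.  Means are censored at t_max and flagged when fewer than
    95% of trials bound.
``binding_fraction_free``
    Cargo starts resting on the microtubule with full translational and
    rotational diffusion; a trial succeeds at first attachment and fails
    at t_max or when the center diffuses beyond the escape radius.
``slab_multi_mt``
    Binding fraction in a z-slab with a single microtubule or an
    infinite periodic array (periodic x-wrapping).
``transport_runs``
    Forced first attachment, full dynamics until every motor is
    detached; yields run lengths, durations and time-averaged engaged
    counts.
``engaged_census``
    Transport runs that accumulate the time-weighted distribution of the
    number of engaged motors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import engine
from .config import WorldConfig
from .core import quat_between, quat_rotate
from .placement import place_motors

_EVENT_NAMES = {engine.EV_ATTACH: "attach", engine.EV_DETACH: "detach",
                engine.EV_STEP: "step"}


@dataclass
class RunResult:
    """Outcome of a single transport run."""

    run_length: float                    # nm, along the plus direction
    duration: float                      # s
    bound_time_first: Optional[float]
    success: bool
    velocity_windows: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    engaged_series: np.ndarray = field(default_factory=lambda: np.empty(0))
    events: Optional[pd.DataFrame] = None
    trajectory: Optional[pd.DataFrame] = None


def _trial_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _geometry_arrays(cfg: WorldConfig):
    if cfg.periodic:
        return np.array([0.0]), float(cfg.x_mt)
    if cfg.x_mt:
        return np.array([0.0, float(cfg.x_mt)]), 0.0
    return np.array([0.0]), 0.0


def _kernel_args(cfg: WorldConfig):
    """Scalar kernel arguments shared by every trial of a protocol."""
    slab = cfg.slab_z if cfg.slab_z is not None else (-1.0e12, 1.0e12)
    return dict(
        R=cfg.R, L0=cfg.L0, k_spring=cfg.k_spring, k_on=cfg.k_on,
        eps0=cfg.eps0, F_d=cfg.F_d, v0=cfg.v0, F_s=cfg.F_s, w_fv=cfg.w,
        K_m=cfg.K_m, atp=cfg.atp, step_nm=cfg.step_nm,
        kBT=cfg.kBT, alpha_T=cfg.alpha_T, alpha_R=cfg.alpha_R,
        F_ext=np.asarray(cfg.F_ext, dtype=float),
        mt_radius=cfg.mt_radius, site_spacing=cfg.site_spacing,
        plus_dir=cfg.plus_dir,
        slab_zmin=float(slab[0]), slab_zmax=float(slab[1]),
        use_slab=cfg.slab_z is not None,
    )


_NO_EVENTS = (np.empty(0), np.empty(0, dtype=np.int64),
              np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64),
              np.empty(0))


def _run_one(cfg, rng, *, anchors, attached, site, bound_mtx, r, q,
             dt, n_steps, freeze_translation, stop_on_first_attach,
             stop_when_all_detached, engaged_time=None, traj=None,
             rec_stride=0, events_cap=0):
    ka = _kernel_args(cfg)
    mt_xs, x_period = _geometry_arrays(cfg)
    if engaged_time is None:
        engaged_time = np.zeros(cfg.n_motors + 1)
    if traj is None:
        traj = np.empty((0, 8))
    if events_cap > 0:
        ev = (np.empty(events_cap), np.empty(events_cap, dtype=np.int64),
              np.empty(events_cap, dtype=np.int64),
              np.empty(events_cap, dtype=np.int64), np.empty(events_cap))
    else:
        ev = _NO_EVENTS
    out = np.zeros(8)
    engine.run_trial(
        r, q, anchors, attached, site, bound_mtx,
        ka["R"], ka["L0"], ka["k_spring"], ka["k_on"], ka["eps0"],
        ka["F_d"], ka["v0"], ka["F_s"], ka["w_fv"], ka["K_m"], ka["atp"],
        ka["step_nm"],
        ka["kBT"], ka["alpha_T"], ka["alpha_R"], ka["F_ext"],
        mt_xs, x_period, ka["mt_radius"], ka["site_spacing"], ka["plus_dir"],
        ka["slab_zmin"], ka["slab_zmax"], ka["use_slab"],
        dt, n_steps,
        cfg.trans_noise, cfg.rot_noise, freeze_translation,
        stop_on_first_attach, stop_when_all_detached,
        float(cfg.escape_radius) if cfg.escape_radius else -1.0,
        engaged_time, traj, rec_stride,
        ev[0], ev[1], ev[2], ev[3], ev[4],
        out, rng,
    )
    events = None
    if events_cap > 0:
        n_ev = int(out[6])
        events = pd.DataFrame({
            "t": ev[0][:n_ev],
            "motor_id": ev[1][:n_ev],
            "event": [_EVENT_NAMES[k] for k in ev[2][:n_ev]],
            "site_index": ev[3][:n_ev],
            "tension_pN": ev[4][:n_ev],
        })
    return out, engaged_time, traj, events


def _fresh_motor_state(cfg, rng):
    anchors = place_motors(cfg.n_motors, cfg.placement, rng, phi=cfg.phi)
    attached = np.zeros(cfg.n_motors, dtype=np.bool_)
    site = np.full(cfg.n_motors, -(2**31), dtype=np.int64)
    bound_mtx = np.zeros(cfg.n_motors)
    return anchors, attached, site, bound_mtx


def _resting_position(cfg) -> np.ndarray:
    return np.array([0.0, 0.0, cfg.R + cfg.mt_radius + cfg.initial_gap_nm])


# ---------------------------------------------------------------------------
# binding protocols
# ---------------------------------------------------------------------------

def binding_time_rotation_only(cfg: WorldConfig, seed: Optional[int] = None,
                               n_trials: Optional[int] = None):
    """Time to first attachment for a cargo held at the microtubule.

    The center stays at the contact point (the cargo cannot diffuse
    away); only rotation evolves.  Returns (per-trial DataFrame,
    summary).  The summary mean is taken over bound trials and flagged
    as censored when fewer than 95% bound within t_max.
    """
    seed = cfg.seed if seed is None else seed
    n_trials = cfg.n_trials if n_trials is None else n_trials
    dt = cfg.effective_dt()
    n_steps = int(round(cfg.t_max / dt))
    rows = []
    for k, rng in enumerate(_trial_rngs(seed, n_trials)):
        anchors, attached, site, bound_mtx = _fresh_motor_state(cfg, rng)
        r = _resting_position(cfg)
        q = np.array([1.0, 0.0, 0.0, 0.0])
        out, _, _, _ = _run_one(
            cfg, rng, anchors=anchors, attached=attached, site=site,
            bound_mtx=bound_mtx, r=r, q=q, dt=dt, n_steps=n_steps,
            freeze_translation=True, stop_on_first_attach=True,
            stop_when_all_detached=False,
        )
        bound = out[0] == engine.STATUS_FIRST_ATTACH
        rows.append({"trial": k, "bound": bound,
                     "t_bind": out[2] if bound else np.nan})
    df = pd.DataFrame(rows)
    return df, _binding_summary_dict(df, cfg, n_trials)


def binding_fraction_free(cfg: WorldConfig, seed: Optional[int] = None,
                          n_trials: Optional[int] = None):
    """Fraction of freely diffusing cargos that bind before escaping."""
    seed = cfg.seed if seed is None else seed
    n_trials = cfg.n_trials if n_trials is None else n_trials
    dt = cfg.effective_dt()
    n_steps = int(round(cfg.t_max / dt))
    rows = []
    for k, rng in enumerate(_trial_rngs(seed, n_trials)):
        anchors, attached, site, bound_mtx = _fresh_motor_state(cfg, rng)
        r = _resting_position(cfg)
        q = np.array([1.0, 0.0, 0.0, 0.0])
        out, _, _, _ = _run_one(
            cfg, rng, anchors=anchors, attached=attached, site=site,
            bound_mtx=bound_mtx, r=r, q=q, dt=dt, n_steps=n_steps,
            freeze_translation=False, stop_on_first_attach=True,
            stop_when_all_detached=False,
        )
        status = int(out[0])
        rows.append({
            "trial": k,
            "success": status == engine.STATUS_FIRST_ATTACH,
            "t_bind": out[2] if status == engine.STATUS_FIRST_ATTACH else np.nan,
            "escaped": status == engine.STATUS_ESCAPED,
            "t_end": out[1],
        })
    df = pd.DataFrame(rows)
    summary = {
        "protocol": "bind_fraction",
        "config_hash": cfg.config_hash(),
        "n_trials": n_trials,
        "fraction_bound": float(df["success"].mean()),
        "n_escaped": int(df["escaped"].sum()),
        "mean_t_bind": float(df.loc[df["success"], "t_bind"].mean())
        if df["success"].any() else None,
    }
    return df, summary


def slab_multi_mt(cfg: WorldConfig, seed: Optional[int] = None,
                  n_trials: Optional[int] = None):
    """Binding fraction in the slab geometry (single or periodic MTs)."""
    if cfg.slab_z is None:
        raise ValueError("slab protocol requires slab_z bounds")
    return binding_fraction_free(cfg, seed=seed, n_trials=n_trials)


def _binding_summary_dict(df: pd.DataFrame, cfg: WorldConfig, n_trials: int):
    n_bound = int(df["bound"].sum())
    frac = n_bound / n_trials
    mean = float(df.loc[df["bound"], "t_bind"].mean()) if n_bound else None
    return {
        "protocol": "bind_time",
        "config_hash": cfg.config_hash(),
        "n_trials": n_trials,
        "n_bound": n_bound,
        "fraction_bound": frac,
        "mean_t_bind": mean,
        "censored": frac < 0.95,
    }


# ---------------------------------------------------------------------------
# transport protocols
# ---------------------------------------------------------------------------

def _forced_attach_init(cfg, rng, mode="all"):
    """Initial condition for transport runs.

    The cargo is rotated so that its best-positioned motor faces the
    microtubule, guaranteeing at least one motor can bind.  In mode
    "all" every motor whose anchor can reach a free binding site then
    binds at t = 0 (each motor takes its initial opportunity to
    attach); in mode "single" only the best-positioned motor binds and
    the rest recruit dynamically.  One head per site in either mode.
    """
    from . import engine as _e

    anchors, attached, site, bound_mtx = _fresh_motor_state(cfg, rng)
    best = int(np.argmin(anchors[:, 2]))  # most downward-pointing anchor
    q = quat_between(anchors[best], np.array([0.0, 0.0, -1.0]))
    # verify the rotation (guards quat_between edge cases)
    a_lab = quat_rotate(q, anchors[best])
    assert a_lab[2] < -0.999
    r = _resting_position(cfg)
    mt_xs, x_period = _geometry_arrays(cfg)
    order = [best] + [i for i in range(cfg.n_motors) if i != best] \
        if mode == "all" else [best]
    for i in order:
        a = r + cfg.R * quat_rotate(q, anchors[i])
        found, j, mtx = _e._nearest_reachable(
            a[0], a[1], a[2], r[0], r[1], r[2], cfg.R,
            mt_xs, x_period, cfg.L0, cfg.mt_radius, cfg.site_spacing,
            i, attached, site, bound_mtx)
        if found:
            attached[i] = True
            site[i] = j
            bound_mtx[i] = mtx
    assert attached.any()
    return anchors, attached, site, bound_mtx, r, q


def transport_runs(cfg: WorldConfig, seed: Optional[int] = None,
                   n_trials: Optional[int] = None,
                   collect_engaged: bool = False):
    """Transport runs until all motors detach (or t_max).

    Returns (per-trial DataFrame, summary).  Run length is the net
    displacement of the cargo center along the microtubule plus
    direction between forced attachment and final detachment; trials
    still attached at t_max are censored (column ``censored``).
    """
    seed = cfg.seed if seed is None else seed
    n_trials = cfg.n_trials if n_trials is None else n_trials
    dt = cfg.effective_dt()
    n_steps = int(round(cfg.t_max / dt))
    engaged_total = np.zeros(cfg.n_motors + 1)
    rows = []
    for k, rng in enumerate(_trial_rngs(seed, n_trials)):
        anchors, attached, site, bound_mtx, r, q = _forced_attach_init(cfg, rng)
        y0 = r[1]
        engaged = np.zeros(cfg.n_motors + 1) if collect_engaged else engaged_total
        out, _, _, _ = _run_one(
            cfg, rng, anchors=anchors, attached=attached, site=site,
            bound_mtx=bound_mtx, r=r, q=q, dt=dt, n_steps=n_steps,
            freeze_translation=False, stop_on_first_attach=False,
            stop_when_all_detached=True, engaged_time=engaged,
        )
        if collect_engaged:
            engaged_total += engaged
        status = int(out[0])
        if status == engine.STATUS_RUNAWAY:
            raise RuntimeError("integrity error: cargo ran away while attached")
        dur = out[1]
        run_len = cfg.plus_dir * (out[3] - y0)
        mean_eng = (np.arange(cfg.n_motors + 1) @ engaged) / engaged.sum() \
            if collect_engaged and engaged.sum() > 0 else np.nan
        rows.append({
            "trial": k,
            "run_length_nm": run_len,
            "duration_s": dur,
            "censored": status == engine.STATUS_TIMEOUT,
            "mean_velocity_nm_s": run_len / dur if dur > 0 else 0.0,
            "mean_engaged": mean_eng,
        })
    df = pd.DataFrame(rows)
    summary = {
        "protocol": "run",
        "config_hash": cfg.config_hash(),
        "n_trials": n_trials,
        "mean_run_length_nm": float(df["run_length_nm"].mean()),
        "n_censored": int(df["censored"].sum()),
        "mean_duration_s": float(df["duration_s"].mean()),
    }
    if collect_engaged:
        tot = engaged_total.sum()
        summary["mean_engaged"] = float(
            np.arange(cfg.n_motors + 1) @ engaged_total / tot) if tot > 0 else None
    return df, summary


def engaged_census(cfg: WorldConfig, seed: Optional[int] = None,
                   n_trials: Optional[int] = None):
    """Time-weighted distribution of the number of engaged motors.

    Runs the transport protocol and accumulates, across all runs, the
    total time spent with each engaged count.  Returns
    (per-trial DataFrame, engaged-time histogram, summary).
    """
    seed = cfg.seed if seed is None else seed
    n_trials = cfg.n_trials if n_trials is None else n_trials
    dt = cfg.effective_dt()
    n_steps = int(round(cfg.t_max / dt))
    hist = np.zeros(cfg.n_motors + 1)
    counts = np.arange(cfg.n_motors + 1)
    rows = []
    for k, rng in enumerate(_trial_rngs(seed, n_trials)):
        # the census watches recruitment build up from the first bound
        # motor, so it starts minimal
        anchors, attached, site, bound_mtx, r, q = _forced_attach_init(
            cfg, rng, mode="single")
        y0 = r[1]
        trial_hist = np.zeros(cfg.n_motors + 1)
        out, _, _, _ = _run_one(
            cfg, rng, anchors=anchors, attached=attached, site=site,
            bound_mtx=bound_mtx, r=r, q=q, dt=dt, n_steps=n_steps,
            freeze_translation=False, stop_on_first_attach=False,
            stop_when_all_detached=True, engaged_time=trial_hist,
        )
        hist += trial_hist
        tw = trial_hist.sum()
        rows.append({
            "trial": k,
            "run_length_nm": cfg.plus_dir * (out[3] - y0),
            "duration_s": out[1],
            "censored": int(out[0]) == engine.STATUS_TIMEOUT,
            "mean_engaged": counts @ trial_hist / tw if tw > 0 else np.nan,
        })
    df = pd.DataFrame(rows)
    total = hist.sum()
    mean = float(counts @ hist / total) if total > 0 else None
    summary = {
        "protocol": "census",
        "config_hash": cfg.config_hash(),
        "n_trials": n_trials,
        "mean_engaged": mean,
        "engaged_time_s": hist.tolist(),
    }
    return df, hist, summary


def transport_run_detailed(cfg: WorldConfig, seed: int,
                           record_stride_s: Optional[float] = None,
                           events_cap: int = 200_000) -> RunResult:
    """One fully instrumented transport run: trajectory, velocity
    windows, engaged-count series, and the event log."""
    dt = cfg.effective_dt()
    n_steps = int(round(cfg.t_max / dt))
    stride_s = record_stride_s or cfg.record_stride_s or 1.0e-3
    rec_stride = max(int(round(stride_s / dt)), 1)
    traj = np.empty((n_steps // rec_stride + 2, 8))
    rng = _trial_rngs(seed, 1)[0]
    anchors, attached, site, bound_mtx, r, q = _forced_attach_init(cfg, rng)
    y0 = r[1]
    engaged = np.zeros(cfg.n_motors + 1)
    out, engaged, traj_full, events = _run_one(
        cfg, rng, anchors=anchors, attached=attached, site=site,
        bound_mtx=bound_mtx, r=r, q=q, dt=dt, n_steps=n_steps,
        freeze_translation=False, stop_on_first_attach=False,
        stop_when_all_detached=True, engaged_time=engaged,
        traj=traj, rec_stride=rec_stride, events_cap=events_cap,
    )
    n_rec = int(out[4])
    tdf = pd.DataFrame(traj[:n_rec],
                       columns=["t", "x", "y", "z", "qw", "qx", "qy", "qz"])
    from .analysis import windowed_velocity
    tau = max(stride_s, 1.0e-3)
    vw = windowed_velocity(tdf["t"].to_numpy(), tdf["y"].to_numpy(), tau,
                           plus_dir=cfg.plus_dir)
    return RunResult(
        run_length=cfg.plus_dir * (out[3] - y0),
        duration=out[1],
        bound_time_first=0.0,
        success=int(out[0]) == engine.STATUS_ALL_DETACHED,
        velocity_windows=vw,
        engaged_series=engaged,
        events=events,
        trajectory=tdf,
    )
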