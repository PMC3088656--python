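"""Per-time-step motor stochastic events: attachment, load-dependent
detachment, and load/ATP-dependent stepping.

Rates:

* attachment: k_on while a binding site is within cable reach of the
  anchor (waiting time exponential with mean 1/k_on);
* detachment: ε(F) = ε₀ exp(F/F_d) with F the full cable tension;
* stepping:   (v0/step) · [ATP]/([ATP]+K_m) · max(0, 1 − (F∥/F_s)^w)
  with F∥ the component of tension opposing plus-end motion (assisting
  loads count as zero); the rate vanishes at or beyond stall.

Per-step event probabilities are p = 1 − exp(−rate·Δt); the stability
rule used by the protocols keeps every p below 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import CargoState, MicrotubuleLattice, MotorState, anchor_position
from .mechanics import site_position


@dataclass(frozen=True)
class KineticRates:
    p_on: float
    p_off: float
    p_step: float


def event_probability(rate: float, dt: float) -> float:
    return float(-np.expm1(-rate * dt))


def reachable_sites(
    cargo: CargoState,
    motor: MotorState,
    mts: Sequence[MicrotubuleLattice],
) -> List[Tuple[MicrotubuleLattice, int]]:
    """All binding sites within binding reach of the anchor.

    Binding requires a straight, unobstructed stalk: the site must be
    within L0 of the anchor along a segment that neither passes through
    the cargo sphere (site on or above the tangent plane at the anchor)
    nor through the microtubule interior (automatic, because the site
    surface point is taken in the anchor's half-plane).  Sites are
    returned sorted by distance (ties by site index).
    """
    from .mechanics import site_position as sp

    if motor.attached:
        raise ValueError("reachable_sites is defined for detached motors")
    a = anchor_position(cargo, motor)
    w = a - cargo.r
    found: List[Tuple[float, int, MicrotubuleLattice]] = []
    for mt in mts:
        d = a - mt.origin
        s_ax = float(np.dot(d, mt.axis))
        j_lo = int(np.ceil((s_ax - motor.L0) / mt.site_spacing))
        j_hi = int(np.floor((s_ax + motor.L0) / mt.site_spacing))
        for j in range(j_lo, j_hi + 1):
            site_pt = sp(mt, j, a)
            v = site_pt - a
            # tolerance: exact tangency is a common degenerate start
            if float(np.dot(v, w)) < -1e-6:
                continue
            dist = float(np.linalg.norm(v))
            if dist <= motor.L0:
                found.append((dist, j, mt))
    found.sort(key=lambda t: (t[0], t[1]))
    return [(mt, j) for _, j, mt in found]


def try_attach(
    motor: MotorState,
    sites: Sequence[Tuple[MicrotubuleLattice, int]],
    dt: float,
    rng: np.random.Generator,
) -> Optional[Tuple[MicrotubuleLattice, int]]:
    """Bernoulli attachment attempt; binds to the nearest reachable site.

    ``sites`` must be ordered as returned by :func:`reachable_sites`.
    """
    if motor.attached:
        raise ValueError("attach attempted while attached")
    if not sites:
        return None
    if rng.random() < event_probability(motor.k_on, dt):
        return sites[0]
    return None


def detach_rate(tension: float, eps0: float, F_d: float) -> float:
    """Load-dependent detachment rate ε(F) = ε₀ exp(F/F_d)."""
    if tension < 0:
        raise ValueError("tension must be nonnegative")
    return eps0 * np.exp(tension / F_d)


def step_rate(
    load_parallel: float,
    v0: float,
    F_s: float,
    atp: float,
    K_m: float,
    step: float = 8.0,
    w: float = 2.0,
) -> float:
    """Stepping rate with Michaelis–Menten ATP dependence and a
    force–velocity factor max(0, 1 − (F∥/F_s)^w)."""
    if atp < 0:
        raise ValueError("ATP concentration must be nonnegative")
    load = max(load_parallel, 0.0)
    if load >= F_s:
        return 0.0
    mm = atp / (atp + K_m) if atp > 0 else 0.0
    return (v0 / step) * mm * (1.0 - (load / F_s) ** w)


def opposing_load(
    tension: float, direction_anchor_to_head: np.ndarray, mt: MicrotubuleLattice
) -> float:
    """Component of the cable pull on the head opposing plus-end motion,
    floored at zero (assisting loads are treated as no load)."""
    pull_on_head = -tension * np.asarray(direction_anchor_to_head)
    opposing = -float(np.dot(pull_on_head, mt.plus_dir * mt.axis))
    return max(opposing, 0.0)


def advance_motors(
    cargo: CargoState,
    motors: Sequence[MotorState],
    mts: Sequence[MicrotubuleLattice],
    dt: float,
    rng: np.random.Generator,
    atp: float = 2000.0,
) -> List[dict]:
    """One Monte Carlo sweep over all motors in fixed index order.

    Loads are evaluated on the pre-event configuration; each attached
    motor samples detachment then (if still attached) a forward step,
    and each detached motor samples attachment to its nearest reachable
    site.  Cargo motion is the caller's responsibility (the cargo is
    moved once afterwards with forces recomputed from the post-event
    state).  Returns the list of events.

    This is the reference implementation of the sweep; the production
    trial loop in :mod:`motorcargo.engine` performs the same updates in
    compiled code.
    """
    from .mechanics import linkage  # local import to avoid cycle at module load

    events: List[dict] = []
    mt = mts[0]
    # pass 1: pre-event loads
    tensions = np.zeros(len(motors))
    loads = np.zeros(len(motors))
    for i, m in enumerate(motors):
        if m.attached:
            a = anchor_position(cargo, m)
            head = site_position(mt, m.site_index, a)
            if np.linalg.norm(head - a) < 1e-9:
                continue  # coincident: slack, no load
            lf = linkage(a, head, m.k_spring, m.L0)
            tensions[i] = lf.tension
            loads[i] = opposing_load(lf.tension, lf.direction, mt)
    # pass 2: events (one motor head per binding site)
    def occupied(j, skip):
        return any(o.attached and o.site_index == j
                   for k, o in enumerate(motors) if k != skip)

    for i, m in enumerate(motors):
        if m.attached:
            if rng.random() < event_probability(detach_rate(tensions[i], m.eps0, m.F_d), dt):
                events.append({"motor": i, "event": "detach", "site": m.site_index,
                               "tension": tensions[i]})
                m.attached = False
                m.site_index = None
            else:
                rs = step_rate(loads[i], m.v0, m.F_s, atp, m.K_m, m.step)
                if rs > 0 and rng.random() < event_probability(rs, dt) \
                        and not occupied(m.site_index + mt.plus_dir, i):
                    m.site_index = m.site_index + mt.plus_dir
                    events.append({"motor": i, "event": "step", "site": m.site_index,
                                   "tension": tensions[i]})
        else:
            sites = [sj for sj in reachable_sites(cargo, m, mts)
                     if not occupied(sj[1], i)]
            hit = try_attach(m, sites, dt, rng)
            if hit is not None:
                _, j = hit
                m.attached = True
                m.site_index = j
                events.append({"motor": i, "event": "attach", "site": j, "tension": 0.0})
    return events
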