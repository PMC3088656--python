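"""Jit-compiled inner loop of the simulator.

One generic kernel drives every protocol.  Per outer time step Δt it

1. computes the cable tension on each attached motor from the current
   geometry,
2. lets every motor attempt its stochastic events (detach, step,
   attach) in fixed index order using those pre-event loads,
3. moves the cargo — translation and rotation — under the forces and
   torques of the post-event configuration, and
4. enforces excluded volume against the microtubule cylinder(s) and
   optional slab walls.

The cargo move uses an exponential (Ornstein–Uhlenbeck) update: the
taut-cable stiffness is linearized into 3×3 translational and
rotational stiffness matrices and the exact OU displacement is taken
per eigenmode.  This is stable for arbitrarily stiff linkages (the
spring relaxation time α/k is far below any affordable Δt) and has the
correct stationary variance kBT/λ in every stiff mode; it reduces to
plain Euler–Maruyama when all cables are slack.  Because the cable law
is nonlinear at the slack/taut boundary, the move is subdivided into
mechanical substeps whenever any attached cable is within a margin of
going taut, so that no single diffusion kick can jump deep into the
taut regime.

Geometry: microtubules are cylinders of radius ``mt_radius`` parallel
to the y axis at z = 0, at the x offsets in ``mt_xs`` (or every
multiple of ``x_period`` when periodic).  Binding site ``j`` sits at
axial coordinate ``j*site_spacing``; its surface point is taken in the
half-plane of the approaching anchor, making the anchor→site distance
exactly ``hypot(rad2d - mt_radius, dy)`` with ``rad2d`` the anchor's
distance to the axis.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# trial status codes
STATUS_TIMEOUT = 0
STATUS_FIRST_ATTACH = 1
STATUS_ALL_DETACHED = 2
STATUS_ESCAPED = 3
STATUS_RUNAWAY = 4

# event codes
EV_ATTACH = 0
EV_DETACH = 1
EV_STEP = 2

# mechanical substepping: subdivide the cargo move when an attached
# cable is within this margin (nm) of its rest length, and aim for
# per-substep position kicks of at most this size (nm) there
_BOUNDARY_MARGIN = 16.0
_KICK_TARGET = 4.0
_MAX_SUBSTEPS = 64


@njit(cache=True)
def _eigh3(A, V, w):
    """Cyclic Jacobi eigendecomposition of a symmetric 3x3 matrix.

    A is destroyed; eigenvectors end up in the columns of V and
    eigenvalues in w.
    """
    for i in range(3):
        for j in range(3):
            V[i, j] = 1.0 if i == j else 0.0
    for _ in range(12):
        off = abs(A[0, 1]) + abs(A[0, 2]) + abs(A[1, 2])
        if off < 1e-14:
            break
        for p in range(2):
            for q in range(p + 1, 3):
                apq = A[p, q]
                if abs(apq) < 1e-18:
                    continue
                theta = 0.5 * (A[q, q] - A[p, p]) / apq
                t = np.sign(theta) / (abs(theta) + np.sqrt(theta * theta + 1.0))
                c = 1.0 / np.sqrt(t * t + 1.0)
                s = t * c
                for k in range(3):
                    akp = A[k, p]
                    akq = A[k, q]
                    A[k, p] = c * akp - s * akq
                    A[k, q] = s * akp + c * akq
                for k in range(3):
                    apk = A[p, k]
                    aqk = A[q, k]
                    A[p, k] = c * apk - s * aqk
                    A[q, k] = s * apk + c * aqk
                for k in range(3):
                    vkp = V[k, p]
                    vkq = V[k, q]
                    V[k, p] = c * vkp - s * vkq
                    V[k, q] = s * vkp + c * vkq
    w[0] = A[0, 0]
    w[1] = A[1, 1]
    w[2] = A[2, 2]


@njit(cache=True)
def _ou_displacement(fx, fy, fz, K, alpha, dt, kBT, noise_on, rng,
                     scratchA, scratchV, scratchw):
    """Exact OU update for drift + noise under linearized stiffness K.

    Per eigenmode with stiffness λ and decay θ = λ·dt/α, the
    deterministic displacement is F·(1−e^{−θ})/λ and the noise variance
    (kBT/λ)(1−e^{−2θ}); both reduce to Euler–Maruyama as λ → 0.
    """
    for i in range(3):
        for j in range(3):
            scratchA[i, j] = K[i, j]
    _eigh3(scratchA, scratchV, scratchw)
    dx = 0.0
    dy = 0.0
    dz = 0.0
    for m in range(3):
        vx = scratchV[0, m]
        vy = scratchV[1, m]
        vz = scratchV[2, m]
        fm = fx * vx + fy * vy + fz * vz
        lam = scratchw[m]
        if lam < 1e-12:
            coef = dt / alpha
            var = 2.0 * kBT * dt / alpha
        else:
            theta = lam * dt / alpha
            coef = -np.expm1(-theta) / lam
            var = kBT * (-np.expm1(-2.0 * theta)) / lam
        um = fm * coef
        if noise_on:
            um += np.sqrt(var) * rng.standard_normal()
        dx += um * vx
        dy += um * vy
        dz += um * vz
    return dx, dy, dz


@njit(cache=True)
def _cable_geometry(axi, ayi, azi, cx, cy, cz, R, sx, sy, sz):
    """Effective cable geometry from an anchor on the cargo sphere to a
    binding-site point, accounting for the cargo's own excluded volume
    (the cable cannot pass through the sphere).

    If the straight anchor→site segment leaves the sphere (site on or
    above the tangent plane at the anchor) the path is direct.
    Otherwise the shortest path wraps: a geodesic arc from the anchor to
    the tangent point plus the straight tangent segment to the site.

    Returns (length, ux, uy, uz, px, py, pz): effective path length, the
    unit pull direction on the cargo (toward the site), and the point on
    the cargo where the pull acts (the anchor when direct, the tangent
    point when wrapped).
    """
    vx = sx - axi
    vy = sy - ayi
    vz = sz - azi
    wx = axi - cx
    wy = ayi - cy
    wz = azi - cz
    if vx * wx + vy * wy + vz * wz >= 0.0:
        ext = np.sqrt(vx * vx + vy * vy + vz * vz)
        if ext < 1e-12:
            return 0.0, 0.0, 0.0, 1.0, axi, ayi, azi
        return ext, vx / ext, vy / ext, vz / ext, axi, ayi, azi
    ex = sx - cx
    ey = sy - cy
    ez = sz - cz
    dc2 = ex * ex + ey * ey + ez * ez
    dc = np.sqrt(dc2)
    cospsi = (wx * ex + wy * ey + wz * ez) / (R * dc)
    if cospsi > 1.0:
        cospsi = 1.0
    elif cospsi < -1.0:
        cospsi = -1.0
    psi = np.arccos(cospsi)
    if dc <= R + 1e-6:
        # site touches the sphere: pure arc, radial pull at the site
        return R * psi, ex / dc, ey / dc, ez / dc, sx, sy, sz
    shx = ex / dc
    shy = ey / dc
    shz = ez / dc
    phit = np.arccos(R / dc)
    lfree = np.sqrt(dc2 - R * R)
    length = lfree + R * (psi - phit)
    # tangent point in the plane of (anchor, center, site), on the
    # anchor's side
    px = wx - R * cospsi * shx
    py = wy - R * cospsi * shy
    pz = wz - R * cospsi * shz
    pn = np.sqrt(px * px + py * py + pz * pz)
    if pn < 1e-9:
        # anchor antipodal to the site direction: any perpendicular
        if abs(shx) < 0.9:
            px = 1.0 - shx * shx
            py = -shx * shy
            pz = -shx * shz
        else:
            px = -shy * shx
            py = 1.0 - shy * shy
            pz = -shy * shz
        pn = np.sqrt(px * px + py * py + pz * pz)
    ehx = px / pn
    ehy = py / pn
    ehz = pz / pn
    ct = R / dc  # cos(phit)
    st = lfree / dc  # sin(phit)
    tx = cx + R * (ct * shx + st * ehx)
    ty = cy + R * (ct * shy + st * ehy)
    tz = cz + R * (ct * shz + st * ehz)
    ux = (sx - tx) / lfree
    uy = (sy - ty) / lfree
    uz = (sz - tz) / lfree
    un = np.sqrt(ux * ux + uy * uy + uz * uz)
    return length, ux / un, uy / un, uz / un, tx, ty, tz


@njit(cache=True, inline="always")
def _ou_rank1(fx, fy, fz, ux, uy, uz, lam, alpha, dt, kBT, noise_on, rng):
    """OU update for a rank-1 stiffness lam·ûûᵀ: exact OU along û,
    Euler–Maruyama in the transverse plane.  Avoids the 3x3
    eigendecomposition for the common single-taut-cable case."""
    theta = lam * dt / alpha
    coef_par = -np.expm1(-theta) / lam
    coef_perp = dt / alpha
    fpar = fx * ux + fy * uy + fz * uz
    dx = ux * fpar * coef_par + (fx - fpar * ux) * coef_perp
    dy = uy * fpar * coef_par + (fy - fpar * uy) * coef_perp
    dz = uz * fpar * coef_par + (fz - fpar * uz) * coef_perp
    if noise_on:
        sd_par = np.sqrt(kBT * (-np.expm1(-2.0 * theta)) / lam)
        sd_perp = np.sqrt(2.0 * kBT * dt / alpha)
        g = rng.standard_normal(3)
        npar = g[0] * ux + g[1] * uy + g[2] * uz
        corr = sd_par * rng.standard_normal() - sd_perp * npar
        dx += sd_perp * g[0] + corr * ux
        dy += sd_perp * g[1] + corr * uy
        dz += sd_perp * g[2] + corr * uz
    return dx, dy, dz


@njit(cache=True, inline="always")
def _nearest_mt_x(x, mt_xs, x_period):
    """x offset of the microtubule axis closest to lab x-coordinate x."""
    if x_period > 0.0:
        return np.rint(x / x_period) * x_period
    best = mt_xs[0]
    bd = abs(x - best)
    for k in range(1, mt_xs.shape[0]):
        d = abs(x - mt_xs[k])
        if d < bd:
            bd = d
            best = mt_xs[k]
    return best


@njit(cache=True, inline="always")
def _site_occupied(j, mtx, self_i, attached, site, bound_mtx):
    """True if another attached motor already occupies site j of the
    microtubule at x offset mtx (one motor head per binding site)."""
    for k in range(attached.shape[0]):
        if k != self_i and attached[k] and site[k] == j \
                and bound_mtx[k] == mtx:
            return True
    return False


@njit(cache=True)
def _nearest_reachable(ax, ay, az, cx, cy, cz, R, mt_xs, x_period, L0,
                       mt_radius, spacing, self_i, attached, site_arr,
                       bound_mtx):
    """Nearest free binding site within binding reach of an anchor.

    Binding requires a straight, unobstructed stalk: the site must be
    within L0 of the anchor along a segment that does not pass through
    the cargo sphere (site on or above the tangent plane at the
    anchor), and must not already hold another motor's head.  Returns
    (found, site_index, mt_x); ties resolve to the lower site index.
    """
    best_len = L0
    found = False
    site = 0
    mtx_out = 0.0
    if x_period > 0.0:
        k0 = int(np.floor(ax / x_period))
        n_cand = 2
    else:
        k0 = 0
        n_cand = mt_xs.shape[0]
    j_lo = int(np.ceil((ay - L0) / spacing))
    j_hi = int(np.floor((ay + L0) / spacing))
    wxa = ax - cx
    wya = ay - cy
    wza = az - cz
    for c in range(n_cand):
        if x_period > 0.0:
            mtx = (k0 + c) * x_period
        else:
            mtx = mt_xs[c]
        dx = ax - mtx
        nr = np.sqrt(dx * dx + az * az)
        if nr < 1e-12:
            sx = mtx
            sz = mt_radius
        else:
            sx = mtx + mt_radius * dx / nr
            sz = mt_radius * az / nr
        for j in range(j_lo, j_hi + 1):
            sy = j * spacing
            # binding needs a straight, cargo-free stalk: the site must
            # lie on or above the tangent plane at the anchor (small
            # tolerance: exact tangency is a common degenerate start)
            vx = sx - ax
            vy = sy - ay
            vz = sz - az
            if vx * wxa + vy * wya + vz * wza < -1e-6:
                continue
            length = np.sqrt(vx * vx + vy * vy + vz * vz)
            if length < best_len or (length <= best_len and not found):
                if _site_occupied(j, mtx, self_i, attached, site_arr,
                                  bound_mtx):
                    continue
                best_len = length
                found = True
                site = j
                mtx_out = mtx
    return found, site, mtx_out


@njit(cache=True, inline="always")
def _head_position(mtx, jsite, spacing, mt_radius, ax, az):
    """Surface point of site j in the half-plane containing the anchor."""
    dx = ax - mtx
    nr = np.sqrt(dx * dx + az * az)
    if nr < 1e-12:
        hx = mtx
        hz = mt_radius
    else:
        hx = mtx + mt_radius * dx / nr
        hz = mt_radius * az / nr
    return hx, jsite * spacing, hz


@njit(cache=True)
def run_trial(
    # state (modified in place)
    r, q, anchors_body, attached, site, bound_mtx,
    # cargo / motor parameters
    R, L0, k_spring, k_on, eps0, F_d, v0, F_s, w_fv, K_m, atp, step_nm,
    # environment
    kBT, alpha_T, alpha_R, F_ext,
    # microtubule geometry
    mt_xs, x_period, mt_radius, site_spacing, plus_dir,
    slab_zmin, slab_zmax, use_slab,
    # integration / protocol
    dt, n_steps,
    trans_noise, rot_noise, freeze_translation,
    stop_on_first_attach, stop_when_all_detached, escape_radius,
    # outputs
    engaged_time, traj, rec_stride,
    ev_t, ev_motor, ev_kind, ev_site, ev_tension,
    out,
    rng,
):
    n = anchors_body.shape[0]
    p_on = -np.expm1(-k_on * dt)
    sigma_T = np.sqrt(2.0 * kBT * dt / alpha_T)
    sigma_R = np.sqrt(2.0 * kBT * dt / alpha_R)
    mm = atp / (atp + K_m) if atp > 0.0 else 0.0
    step_rate0 = (v0 / step_nm) * mm

    # substep count used near the slack/taut cable boundary, sized so a
    # single kick (translation or surface rotation) stays below target
    kick = sigma_T if sigma_T > sigma_R * R else sigma_R * R
    m_boundary = int(np.ceil((kick / _KICK_TARGET) ** 2))
    if m_boundary < 1:
        m_boundary = 1
    if m_boundary > _MAX_SUBSTEPS:
        m_boundary = _MAX_SUBSTEPS

    ax = np.empty(n)
    ay = np.empty(n)
    az = np.empty(n)
    tension = np.zeros(n)
    loadpar = np.zeros(n)
    KT = np.empty((3, 3))
    KR = np.empty((3, 3))
    sA = np.empty((3, 3))
    sV = np.empty((3, 3))
    sw = np.empty(3)
    active = np.empty(n, dtype=np.int64)

    max_ev = ev_t.shape[0]
    n_ev = 0
    n_rec = 0
    if rec_stride > 0 and traj.shape[0] > 0:
        traj[0, 0] = 0.0
        traj[0, 1] = r[0]
        traj[0, 2] = r[1]
        traj[0, 3] = r[2]
        traj[0, 4] = q[0]
        traj[0, 5] = q[1]
        traj[0, 6] = q[2]
        traj[0, 7] = q[3]
        n_rec = 1

    status = STATUS_TIMEOUT
    first_attach_t = -1.0
    t_end = n_steps * dt
    n_eng = 0
    ever_attached = False
    for i in range(n):
        if attached[i]:
            ever_attached = True

    for s in range(n_steps):
        # rotation matrix from quaternion (body -> lab)
        qw = q[0]; qx = q[1]; qy = q[2]; qz = q[3]
        r00 = 1.0 - 2.0 * (qy * qy + qz * qz)
        r01 = 2.0 * (qx * qy - qw * qz)
        r02 = 2.0 * (qx * qz + qw * qy)
        r10 = 2.0 * (qx * qy + qw * qz)
        r11 = 1.0 - 2.0 * (qx * qx + qz * qz)
        r12 = 2.0 * (qy * qz - qw * qx)
        r20 = 2.0 * (qx * qz - qw * qy)
        r21 = 2.0 * (qy * qz + qw * qx)
        r22 = 1.0 - 2.0 * (qx * qx + qy * qy)
        for i in range(n):
            bx = anchors_body[i, 0]
            by = anchors_body[i, 1]
            bz = anchors_body[i, 2]
            ax[i] = r[0] + R * (r00 * bx + r01 * by + r02 * bz)
            ay[i] = r[1] + R * (r10 * bx + r11 * by + r12 * bz)
            az[i] = r[2] + R * (r20 * bx + r21 * by + r22 * bz)

        # ---- pass 1: loads from the pre-event configuration -------------
        for i in range(n):
            if attached[i]:
                hx, hy, hz = _head_position(
                    bound_mtx[i], site[i], site_spacing, mt_radius, ax[i], az[i]
                )
                ext, ux, uy, uz, _, _, _ = _cable_geometry(
                    ax[i], ay[i], az[i], r[0], r[1], r[2], R, hx, hy, hz)
                if ext > L0:
                    tension[i] = k_spring * (ext - L0)
                    # the cable pulls the head backward along -u; the
                    # component against plus-end motion is the opposing load
                    back = plus_dir * uy
                    loadpar[i] = tension[i] * back if back > 0.0 else 0.0
                else:
                    tension[i] = 0.0
                    loadpar[i] = 0.0

        # ---- pass 2: stochastic events, fixed index order ----------------
        for i in range(n):
            if attached[i]:
                rate_off = eps0 * np.exp(tension[i] / F_d)
                if rng.random() < -np.expm1(-rate_off * dt):
                    attached[i] = False
                    if n_ev < max_ev:
                        ev_t[n_ev] = (s + 1) * dt
                        ev_motor[n_ev] = i
                        ev_kind[n_ev] = EV_DETACH
                        ev_site[n_ev] = site[i]
                        ev_tension[n_ev] = tension[i]
                        n_ev += 1
                    site[i] = -(2**31)
                else:
                    if loadpar[i] < F_s:
                        frac = 1.0 - (loadpar[i] / F_s) ** w_fv
                        rate_s = step_rate0 * frac
                        if rate_s > 0.0 and rng.random() < -np.expm1(-rate_s * dt) \
                                and not _site_occupied(
                                    site[i] + plus_dir, bound_mtx[i], i,
                                    attached, site, bound_mtx):
                            site[i] += plus_dir
                            if n_ev < max_ev:
                                ev_t[n_ev] = (s + 1) * dt
                                ev_motor[n_ev] = i
                                ev_kind[n_ev] = EV_STEP
                                ev_site[n_ev] = site[i]
                                ev_tension[n_ev] = tension[i]
                                n_ev += 1
            else:
                if rng.random() < p_on:
                    found, j, mtx = _nearest_reachable(
                        ax[i], ay[i], az[i], r[0], r[1], r[2], R,
                        mt_xs, x_period, L0, mt_radius, site_spacing,
                        i, attached, site, bound_mtx,
                    )
                    if found:
                        attached[i] = True
                        site[i] = j
                        bound_mtx[i] = mtx
                        ever_attached = True
                        if n_ev < max_ev:
                            ev_t[n_ev] = (s + 1) * dt
                            ev_motor[n_ev] = i
                            ev_kind[n_ev] = EV_ATTACH
                            ev_site[n_ev] = j
                            ev_tension[n_ev] = 0.0
                            n_ev += 1

        n_eng = 0
        for i in range(n):
            if attached[i]:
                n_eng += 1
        engaged_time[n_eng] += dt
        t_next = (s + 1) * dt

        if n_eng > 0 and first_attach_t < 0.0:
            first_attach_t = t_next
        if stop_on_first_attach and n_eng > 0:
            status = STATUS_FIRST_ATTACH
            t_end = t_next
            break
        if stop_when_all_detached and ever_attached and n_eng == 0:
            status = STATUS_ALL_DETACHED
            t_end = t_next
            break

        # ---- pass 3: move the cargo under post-event forces --------------
        # shortlist the motors that can exert force during this step:
        # attached cables within the boundary margin of going taut (a
        # slack cable further away cannot turn taut within one move)
        n_active = 0
        if n_eng > 0:
            for i in range(n):
                if attached[i]:
                    hx, hy, hz = _head_position(
                        bound_mtx[i], site[i], site_spacing, mt_radius,
                        ax[i], az[i])
                    ext, _, _, _, _, _, _ = _cable_geometry(
                        ax[i], ay[i], az[i], r[0], r[1], r[2], R, hx, hy, hz)
                    if ext > L0 - _BOUNDARY_MARGIN:
                        active[n_active] = i
                        n_active += 1
        m_sub = m_boundary if n_active > 0 else 1
        dt_sub = dt / m_sub

        for sub in range(m_sub):
            if sub > 0:
                # refresh geometry after the previous substep
                qw = q[0]; qx = q[1]; qy = q[2]; qz = q[3]
                r00 = 1.0 - 2.0 * (qy * qy + qz * qz)
                r01 = 2.0 * (qx * qy - qw * qz)
                r02 = 2.0 * (qx * qz + qw * qy)
                r10 = 2.0 * (qx * qy + qw * qz)
                r11 = 1.0 - 2.0 * (qx * qx + qz * qz)
                r12 = 2.0 * (qy * qz - qw * qx)
                r20 = 2.0 * (qx * qz - qw * qy)
                r21 = 2.0 * (qy * qz + qw * qx)
                r22 = 1.0 - 2.0 * (qx * qx + qy * qy)
                for ia in range(n_active):
                    i = active[ia]
                    bx = anchors_body[i, 0]
                    by = anchors_body[i, 1]
                    bz = anchors_body[i, 2]
                    ax[i] = r[0] + R * (r00 * bx + r01 * by + r02 * bz)
                    ay[i] = r[1] + R * (r10 * bx + r11 * by + r12 * bz)
                    az[i] = r[2] + R * (r20 * bx + r21 * by + r22 * bz)

            fx = F_ext[0]; fy = F_ext[1]; fz = F_ext[2]
            tqx = 0.0; tqy = 0.0; tqz = 0.0
            n_taut = 0
            u1x = 0.0; u1y = 0.0; u1z = 0.0
            c1x = 0.0; c1y = 0.0; c1z = 0.0
            for i in range(3):
                for j3 in range(3):
                    KT[i, j3] = 0.0
                    KR[i, j3] = 0.0
            for ia in range(n_active):
                i = active[ia]
                if True:
                    hx, hy, hz = _head_position(
                        bound_mtx[i], site[i], site_spacing, mt_radius,
                        ax[i], az[i])
                    ext, ux, uy, uz, px, py, pz = _cable_geometry(
                        ax[i], ay[i], az[i], r[0], r[1], r[2], R, hx, hy, hz)
                    if ext > L0:
                        n_taut += 1
                        ften = k_spring * (ext - L0)
                        fix = ften * ux
                        fiy = ften * uy
                        fiz = ften * uz
                        fx += fix
                        fy += fiy
                        fz += fiz
                        # the pull acts at the anchor (direct path) or at
                        # the tangent point (wrapped path)
                        lx = px - r[0]
                        ly = py - r[1]
                        lz = pz - r[2]
                        tqx += ly * fiz - lz * fiy
                        tqy += lz * fix - lx * fiz
                        tqz += lx * fiy - ly * fix
                        # longitudinal cable stiffness k along the unit
                        # pull direction, and its rotational image
                        KT[0, 0] += k_spring * ux * ux
                        KT[0, 1] += k_spring * ux * uy
                        KT[0, 2] += k_spring * ux * uz
                        KT[1, 1] += k_spring * uy * uy
                        KT[1, 2] += k_spring * uy * uz
                        KT[2, 2] += k_spring * uz * uz
                        cx = ly * uz - lz * uy
                        cy = lz * ux - lx * uz
                        cz = lx * uy - ly * ux
                        KR[0, 0] += k_spring * cx * cx
                        KR[0, 1] += k_spring * cx * cy
                        KR[0, 2] += k_spring * cx * cz
                        KR[1, 1] += k_spring * cy * cy
                        KR[1, 2] += k_spring * cy * cz
                        KR[2, 2] += k_spring * cz * cz
                        u1x = ux; u1y = uy; u1z = uz
                        c1x = cx; c1y = cy; c1z = cz
            if n_taut > 1:
                KT[1, 0] = KT[0, 1]; KT[2, 0] = KT[0, 2]; KT[2, 1] = KT[1, 2]
                KR[1, 0] = KR[0, 1]; KR[2, 0] = KR[0, 2]; KR[2, 1] = KR[1, 2]

            if not freeze_translation:
                if n_taut == 0:
                    r[0] += fx / alpha_T * dt_sub
                    r[1] += fy / alpha_T * dt_sub
                    r[2] += fz / alpha_T * dt_sub
                    if trans_noise:
                        amp = np.sqrt(2.0 * kBT * dt_sub / alpha_T)
                        g = rng.standard_normal(3)
                        r[0] += amp * g[0]
                        r[1] += amp * g[1]
                        r[2] += amp * g[2]
                elif n_taut == 1:
                    ddx, ddy, ddz = _ou_rank1(
                        fx, fy, fz, u1x, u1y, u1z, k_spring, alpha_T,
                        dt_sub, kBT, trans_noise, rng)
                    r[0] += ddx
                    r[1] += ddy
                    r[2] += ddz
                else:
                    ddx, ddy, ddz = _ou_displacement(
                        fx, fy, fz, KT, alpha_T, dt_sub, kBT, trans_noise,
                        rng, sA, sV, sw)
                    r[0] += ddx
                    r[1] += ddy
                    r[2] += ddz

            if n_taut == 0:
                wx = tqx / alpha_R * dt_sub
                wy = tqy / alpha_R * dt_sub
                wz = tqz / alpha_R * dt_sub
                if rot_noise:
                    amp = np.sqrt(2.0 * kBT * dt_sub / alpha_R)
                    g = rng.standard_normal(3)
                    wx += amp * g[0]
                    wy += amp * g[1]
                    wz += amp * g[2]
            elif n_taut == 1:
                c2 = c1x * c1x + c1y * c1y + c1z * c1z
                if c2 < 1e-12:
                    wx = tqx / alpha_R * dt_sub
                    wy = tqy / alpha_R * dt_sub
                    wz = tqz / alpha_R * dt_sub
                    if rot_noise:
                        amp = np.sqrt(2.0 * kBT * dt_sub / alpha_R)
                        g = rng.standard_normal(3)
                        wx += amp * g[0]
                        wy += amp * g[1]
                        wz += amp * g[2]
                else:
                    cn = np.sqrt(c2)
                    wx, wy, wz = _ou_rank1(
                        tqx, tqy, tqz, c1x / cn, c1y / cn, c1z / cn,
                        k_spring * c2, alpha_R, dt_sub, kBT, rot_noise, rng)
            else:
                wx, wy, wz = _ou_displacement(
                    tqx, tqy, tqz, KR, alpha_R, dt_sub, kBT, rot_noise,
                    rng, sA, sV, sw)
            theta = np.sqrt(wx * wx + wy * wy + wz * wz)
            if theta > 0.0:
                half = 0.5 * theta
                sc = np.sin(half) / theta
                pw = np.cos(half); px = wx * sc; py = wy * sc; pz = wz * sc
                qw = q[0]; qx = q[1]; qy = q[2]; qz = q[3]
                nw = pw * qw - px * qx - py * qy - pz * qz
                nx = pw * qx + px * qw + py * qz - pz * qy
                ny = pw * qy - px * qz + py * qw + pz * qx
                nz = pw * qz + px * qy - py * qx + pz * qw
                norm = np.sqrt(nw * nw + nx * nx + ny * ny + nz * nz)
                q[0] = nw / norm
                q[1] = nx / norm
                q[2] = ny / norm
                q[3] = nz / norm

            if not freeze_translation:
                # excluded volume against the nearest microtubule cylinder
                mtx = _nearest_mt_x(r[0], mt_xs, x_period)
                dxc = r[0] - mtx
                rad = np.sqrt(dxc * dxc + r[2] * r[2])
                rmin = R + mt_radius
                if rad < rmin:
                    if rad < 1e-9:
                        r[0] = mtx
                        r[2] = rmin
                    else:
                        r[0] = mtx + dxc * rmin / rad
                        r[2] = r[2] * rmin / rad
                if use_slab:
                    if r[2] + R > slab_zmax:
                        r[2] = slab_zmax - R
                    if r[2] - R < slab_zmin:
                        r[2] = slab_zmin + R

        if not freeze_translation:
            if x_period > 0.0 and n_eng == 0:
                # re-centre on the nearest image once untethered
                r[0] -= np.rint(r[0] / x_period) * x_period
            if escape_radius > 0.0 and n_eng == 0:
                mtx = _nearest_mt_x(r[0], mt_xs, x_period)
                dxc = r[0] - mtx
                if np.sqrt(dxc * dxc + r[2] * r[2]) > escape_radius:
                    status = STATUS_ESCAPED
                    t_end = t_next
                    break

        if n_eng > 0 and (s & 1023) == 0:
            mtx = _nearest_mt_x(r[0], mt_xs, x_period)
            dxc = r[0] - mtx
            if np.sqrt(dxc * dxc + r[2] * r[2]) > 1.0e4:
                status = STATUS_RUNAWAY
                t_end = t_next
                break

        if rec_stride > 0 and ((s + 1) % rec_stride) == 0 and n_rec < traj.shape[0]:
            traj[n_rec, 0] = t_next
            traj[n_rec, 1] = r[0]
            traj[n_rec, 2] = r[1]
            traj[n_rec, 3] = r[2]
            traj[n_rec, 4] = q[0]
            traj[n_rec, 5] = q[1]
            traj[n_rec, 6] = q[2]
            traj[n_rec, 7] = q[3]
            n_rec += 1

        out[5] = s + 1.0

    out[0] = status
    out[1] = t_end
    out[2] = first_attach_t
    out[3] = r[1]
    out[4] = n_rec
    out[6] = n_ev
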