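"""Motor event kinetics: reach geometry, attachment, detachment,
stepping, and the reference Monte Carlo sweep."""

import numpy as np
import pytest

from motorcargo.core import CargoState, MicrotubuleLattice, MotorState
from motorcargo.kinetics import (
    advance_motors,
    detach_rate,
    event_probability,
    reachable_sites,
    step_rate,
    try_attach,
)


@pytest.fixture
def mt():
    return MicrotubuleLattice()


def resting_cargo(R, gap=0.0):
    return CargoState(r=[0.0, 0.0, R + 12.5 + gap], R=R)


class TestReachableSites:
    def test_south_pole_in_contact_reaches(self, mt):
        cargo = resting_cargo(250.0)
        m = MotorState(anchor_body=[0.0, 0.0, -1.0])
        sites = reachable_sites(cargo, m, [mt])
        assert len(sites) >= 1
        # nearest first: site 0 at distance 0
        assert sites[0][1] == 0

    def test_north_pole_of_large_cargo_cannot_reach(self, mt):
        cargo = resting_cargo(250.0)
        m = MotorState(anchor_body=[0.0, 0.0, 1.0])
        assert reachable_sites(cargo, m, [mt]) == []

    def test_reach_fraction_matches_geometric_oracle(self, mt, rng):
        # fraction of uniform anchors with >= 1 reachable site for a
        # 50 nm cargo resting on the MT, vs an independent vectorized
        # Monte Carlo integral of the same binding criterion: a straight
        # stalk of length <= L0 that does not cut through the cargo
        R, L0 = 50.0, 110.0
        cargo = resting_cargo(R)
        n = 2000
        u = rng.standard_normal((n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        anchors = cargo.r + R * u

        def line_of_sight_reach(a):
            nr = np.hypot(a[0], a[2])
            sxz = 12.5 * np.array([a[0], a[2]]) / nr
            w = a - cargo.r
            for j in range(-20, 21):
                s = np.array([sxz[0], 8.0 * j, sxz[1]])
                v = s - a
                if np.dot(v, w) >= 0 and np.linalg.norm(v) <= L0:
                    return True
            return False

        oracle_frac = np.mean([line_of_sight_reach(a) for a in anchors])
        hits = 0
        for i in range(400):
            m = MotorState(anchor_body=u[i])
            if reachable_sites(cargo, m, [mt]):
                hits += 1
        assert hits / 400 == pytest.approx(oracle_frac, abs=0.07)
        # cargo shadowing matters at this radius: the far hemisphere
        # cannot bind even though the straight chord would be short
        assert 0.4 < oracle_frac < 0.85


class TestTryAttach:
    def test_probability_small_dt(self, mt):
        assert event_probability(2.0, 1e-4) == pytest.approx(2.0e-4, rel=1e-3)

    def test_empty_sites_never_binds(self, mt, rng):
        m = MotorState()
        assert try_attach(m, [], 1e-4, rng) is None

    def test_waiting_time_exponential_mean(self, mt, rng):
        # mean waiting time while continuously in reach = 1/k_on = 0.5 s
        dt = 1e-3
        m = MotorState(k_on=2.0)
        sites = [(mt, 0)]
        waits = []
        for _ in range(500):
            t = 0.0
            while True:
                t += dt
                if try_attach(m, sites, dt, rng) is not None:
                    break
            waits.append(t)
        assert np.mean(waits) == pytest.approx(0.5, rel=0.15)

    def test_attach_while_attached_is_error(self, mt, rng):
        m = MotorState(attached=True, site_index=0)
        with pytest.raises(ValueError):
            try_attach(m, [(mt, 0)], 1e-4, rng)


class TestRates:
    def test_detach_rate_limits(self):
        assert detach_rate(0.0, 1.0, 4.0) == pytest.approx(1.0)
        assert detach_rate(4.0, 1.0, 4.0) == pytest.approx(np.e)
        with pytest.raises(ValueError):
            detach_rate(-1.0, 1.0, 4.0)

    def test_detach_rate_monotone(self):
        f = np.linspace(0, 10, 50)
        r = [detach_rate(x, 1.0, 4.0) for x in f]
        assert (np.diff(r) > 0).all()

    def test_step_rate_saturating_atp(self):
        # rate = v0/step at saturating ATP and zero load
        assert step_rate(0.0, 800.0, 6.0, atp=1e9, K_m=50.0) == pytest.approx(100.0)

    def test_step_rate_stall(self):
        assert step_rate(6.0, 800.0, 6.0, atp=1e9, K_m=50.0) == 0.0
        assert step_rate(8.0, 800.0, 6.0, atp=1e9, K_m=50.0) == 0.0

    def test_step_rate_mm_midpoint(self):
        assert step_rate(0.0, 800.0, 6.0, atp=50.0, K_m=50.0) == pytest.approx(50.0)

    def test_step_rate_monotone(self):
        loads = np.linspace(0, 6, 30)
        r = [step_rate(f, 800.0, 6.0, atp=2000.0, K_m=50.0) for f in loads]
        assert (np.diff(r) < 0).all()
        atps = np.linspace(1, 2000, 30)
        r = [step_rate(0.0, 800.0, 6.0, atp=a, K_m=50.0) for a in atps]
        assert (np.diff(r) > 0).all()


class TestAdvanceMotors:
    def test_out_of_reach_motors_unchanged(self, mt, rng):
        cargo = resting_cargo(250.0)
        motors = [MotorState(anchor_body=[0.0, 0.0, 1.0]) for _ in range(3)]
        for _ in range(100):
            advance_motors(cargo, motors, [mt], 1e-4, rng)
        assert not any(m.attached for m in motors)

    def test_zero_rates_keep_head_stationary(self, mt, rng):
        cargo = resting_cargo(100.0)
        m = MotorState(anchor_body=[0.0, 0.0, -1.0], attached=True,
                       site_index=0, eps0=0.0, v0=0.0, k_on=0.0)
        for _ in range(200):
            advance_motors(cargo, [m], [mt], 1e-4, rng)
        assert m.attached and m.site_index == 0

    def test_event_frequencies_match_rates(self, mt, rng):
        # attachment counting oracle: an always-in-reach motor binds at
        # k_on; binomial 3-sigma check over many sweeps
        cargo = resting_cargo(100.0)
        dt = 1e-3
        n_sweeps = 20000
        attaches = 0
        for _ in range(n_sweeps):
            m = MotorState(anchor_body=[0.0, 0.0, -1.0], k_on=2.0)
            if advance_motors(cargo, [m], [mt], dt, rng):
                attaches += 1
        p = event_probability(2.0, dt)
        se = np.sqrt(n_sweeps * p * (1 - p))
        assert abs(attaches - n_sweeps * p) < 3 * se
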