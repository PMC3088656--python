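"""Diffusion statistics of the overdamped integrator, and agreement
with the inertial (underdamped) oracle."""

import numpy as np
import pytest
from scipy import stats

from motorcargo.brownian import drag, inertial_translation_oracle, step_rotation, step_translation
from motorcargo.core import CargoState, Environment, quat_rotate


class TestDrag:
    def test_closed_forms(self):
        d = drag(500.0, 1e-9)
        assert d.alpha_T == pytest.approx(6 * np.pi * 1e-9 * 500, rel=1e-12)
        assert d.alpha_T == pytest.approx(9.4248e-6, rel=1e-4)
        assert d.alpha_R == pytest.approx(3.1416, rel=1e-4)

    def test_radius_viscosity_tradeoff(self):
        # R=500 at 1x and R=250 at 2x share alpha_T but alpha_R differs 4x
        big = drag(500.0, 1e-9)
        small = drag(250.0, 2e-9)
        assert big.alpha_T == pytest.approx(small.alpha_T, rel=1e-12)
        assert big.alpha_R == pytest.approx(4.0 * small.alpha_R, rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            drag(0.0, 1e-9)
        with pytest.raises(ValueError):
            drag(100.0, -1e-9)


class TestStepTranslation:
    def test_noise_off_force_free_is_identity(self, rng):
        cargo = CargoState(r=[1.0, 2.0, 3.0], R=250.0)
        r = step_translation(cargo, np.zeros(3), 1e-4, Environment(), rng,
                             noise_on=False)
        np.testing.assert_allclose(r, cargo.r)

    def test_deterministic_drift(self, rng):
        cargo = CargoState(r=np.zeros(3), R=500.0)
        r = step_translation(cargo, np.array([0.0, 1.0, 0.0]), 1e-4,
                             Environment(), rng, noise_on=False)
        assert r[1] == pytest.approx(1e-4 / 9.4248e-6, rel=1e-4)  # 10.61 nm

    def test_einstein_relation(self, rng):
        # <|dr|^2> = 6 D t for a free cargo, within 3 SE
        env = Environment()
        cargo = CargoState(r=np.zeros(3), R=250.0)
        alpha = drag(cargo.R, env.eta).alpha_T
        dt, n_steps, n_walkers = 1e-4, 100, 1000
        disp = np.zeros((n_walkers, 3))
        for _ in range(n_steps):
            sigma = np.sqrt(2 * env.kBT * dt / alpha)
            disp += sigma * rng.standard_normal((n_walkers, 3))
        sq = (disp**2).sum(axis=1)
        expected = 6 * (env.kBT / alpha) * (n_steps * dt)
        se = sq.std(ddof=1) / np.sqrt(n_walkers)
        assert abs(sq.mean() - expected) < 3 * se


class TestStepRotation:
    def test_no_torque_no_noise_keeps_orientation(self, rng):
        cargo = CargoState(R=500.0)
        q = step_rotation(cargo, np.zeros(3), 1e-3, Environment(), rng,
                          noise_on=False)
        np.testing.assert_allclose(q, [1, 0, 0, 0])

    def test_deterministic_torque_drift(self, rng):
        cargo = CargoState(R=500.0)
        q = step_rotation(cargo, np.array([1.0, 0.0, 0.0]), 1e-3,
                          Environment(), rng, noise_on=False)
        angle = 2 * np.arccos(np.clip(q[0], -1, 1))
        assert angle == pytest.approx(1e-3 / 3.1416, rel=1e-3)  # 3.18e-4 rad

    def test_rotational_decorrelation(self, rng):
        # <u(t).u(0)> = exp(-2 D_R t) for a freely rotating sphere
        env = Environment()
        R = 250.0
        alpha_R = drag(R, env.eta).alpha_R
        D_R = env.kBT / alpha_R
        dt = 5e-4
        n_steps = 40
        n_walkers = 800
        u = np.tile(np.array([0.0, 0.0, 1.0]), (n_walkers, 1))
        sigma = np.sqrt(2 * env.kBT * dt / alpha_R)
        for _ in range(n_steps):
            w = sigma * rng.standard_normal((n_walkers, 3))
            theta = np.linalg.norm(w, axis=1, keepdims=True)
            axis = w / np.where(theta > 0, theta, 1.0)
            c = np.cos(theta)
            s = np.sin(theta)
            u = (u * c + np.cross(axis, u) * s
                 + axis * (axis * u).sum(axis=1, keepdims=True) * (1 - c))
        corr = u[:, 2]
        expected = np.exp(-2 * D_R * n_steps * dt)
        se = corr.std(ddof=1) / np.sqrt(n_walkers)
        assert abs(corr.mean() - expected) < 3 * se


class TestInertialOracle:
    def test_terminal_drift_velocity(self, rng):
        cargo = CargoState(R=500.0, mass_density=1000.0)
        env = Environment()
        alpha = drag(cargo.R, env.eta).alpha_T
        tau = cargo.mass / alpha
        F = np.array([0.0, 2.0, 0.0])
        n_inner = 2000
        x = inertial_translation_oracle(cargo.mass, alpha, env.kBT, F,
                                        dt_small=tau / 50, n_inner=n_inner,
                                        n_samples=1, rng=rng, noise_on=False)
        T = n_inner * tau / 50
        v_mean = x[0, 1] / T
        # from rest, the mean velocity over T carries the start-up
        # transient: <v> = (F/alpha)(1 - (tau/T)(1 - e^(-T/tau)))
        expected = F[1] / alpha * (1 - (tau / T) * (1 - np.exp(-T / tau)))
        assert v_mean == pytest.approx(expected, rel=1e-2)

    @pytest.mark.parametrize("R", [50.0, 500.0])
    def test_overdamped_matches_coarse_grained_inertial(self, R, rng):
        # displacement marginals over dt agree (KS p > 0.01)
        cargo = CargoState(R=R, mass_density=1000.0)
        env = Environment()
        alpha = drag(R, env.eta).alpha_T
        tau = cargo.mass / alpha
        dt = 1e-5
        n_inner = max(int(dt / (tau / 20)), 10)
        n_samples = 400
        x_in = inertial_translation_oracle(
            cargo.mass, alpha, env.kBT, np.zeros(3), dt_small=dt / n_inner,
            n_inner=n_inner, n_samples=n_samples, rng=rng)
        sigma = np.sqrt(2 * env.kBT * dt / alpha)
        x_od = sigma * rng.standard_normal(n_samples)
        res = stats.ks_2samp(x_in[:, 0], x_od)
        assert res.pvalue > 0.01

    def test_equipartition(self, rng):
        # velocity variance kBT/m per axis at equilibrium
        cargo = CargoState(R=500.0, mass_density=1000.0)
        env = Environment()
        alpha = drag(cargo.R, env.eta).alpha_T
        m = cargo.mass
        tau = m / alpha
        dt_small = tau / 50
        n_samples = 2000
        v = rng.standard_normal((n_samples, 3)) * np.sqrt(env.kBT / m)
        amp = np.sqrt(2 * env.kBT * alpha * dt_small) / m
        for _ in range(500):
            v += -alpha * v * dt_small / m + amp * rng.standard_normal((n_samples, 3))
        var = v.var(ddof=1)
        se = var * np.sqrt(2.0 / (3 * n_samples))
        assert abs(var - env.kBT / m) < 4 * se
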