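"""IGSO3 schedule, density, sampler, score and reverse integration."""

import numpy as np
import pytest
from scipy.stats import ks_2samp, kstest

from idpensemble import geometry as G
from idpensemble import so3


SCHED = so3.SO3Schedule()


class TestSchedule:
    def test_endpoints(self):
        assert np.isclose(so3.sigma(0.0, SCHED), 0.1)
        assert np.isclose(so3.sigma(1.0, SCHED), 1.5)

    def test_midpoint_value(self):
        # log(0.5 e^1.5 + 0.5 e^0.1)
        assert np.isclose(so3.sigma(0.5, SCHED), 1.0272702293585056, atol=1e-10)

    def test_monotone(self):
        t = np.linspace(0, 1, 101)
        s = so3.sigma(t, SCHED)
        assert np.all(np.diff(s) > 0)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            so3.sigma(1.5, SCHED)
        with pytest.raises(ValueError):
            so3.sigma(-0.1, SCHED)

    def test_g_squared_integrates_to_twice_sigma_sq(self):
        # int_0^t g^2 = 2 (sigma^2(t) - sigma^2(0)): Brownian time of the kernel
        t = np.linspace(0, 1, 20001)
        integral = np.trapezoid(so3.g_squared(t, SCHED), t)
        expected = 2 * (so3.sigma(1.0, SCHED) ** 2 - so3.sigma(0.0, SCHED) ** 2)
        assert np.isclose(integral, expected, rtol=1e-6)


class TestDensity:
    def test_large_sigma_approaches_haar(self):
        om = np.linspace(0.01, np.pi, 200)
        haar = (1 - np.cos(om)) / np.pi
        assert np.abs(so3.igso3_density(om, 20.0) - haar).max() < 1e-3

    @pytest.mark.parametrize("sig", [0.1, 0.5, 1.5])
    def test_normalization(self, sig):
        om = np.linspace(1e-6, np.pi, 4000)
        mass = np.trapezoid(so3.igso3_density(om, sig), om)
        assert abs(mass - 1.0) < 1e-3

    def test_small_sigma_mean_matches_tangent_gaussian(self):
        # oracle: norm of an isotropic 3D Gaussian (std sqrt(2)*sigma per axis)
        sig = 0.05
        om = np.linspace(1e-6, np.pi, 40000)
        d = so3.igso3_density(om, sig)
        mean = np.trapezoid(om * d, om) / np.trapezoid(d, om)
        chi3_mean = np.sqrt(2) * sig * 2 * np.sqrt(2 / np.pi)
        assert abs(mean - chi3_mean) / chi3_mean < 0.02

    def test_table_cdf_properties(self, igso3_table):
        assert np.all(np.diff(igso3_table.cdf, axis=1) >= -1e-12)
        assert np.allclose(igso3_table.cdf[:, -1], 1.0, atol=1e-4)
        assert np.all(igso3_table.density >= 0)
        assert igso3_table.norm_error.max() < 1e-3


class TestSampler:
    @pytest.mark.parametrize("sig", [0.1, 0.5, 1.0, 1.5])
    def test_inverse_cdf_sampling_matches_density(self, igso3_table, sig):
        rng = np.random.default_rng(42)
        ang = igso3_table.sample_angles(sig, 50_000, rng)
        ks = kstest(ang, lambda x: igso3_table.cdf_fn(x, sig))
        assert ks.statistic < 0.015

    def test_zero_noise_limit_returns_start(self, igso3_table):
        sched = so3.SO3Schedule(sigma_min=0.021, sigma_max=1.5)
        rng = np.random.default_rng(0)
        R0 = G.random_rotation(rng, 50)
        Rt = so3.sample_igso3(R0, 0.0, sched, igso3_table, rng)
        ang = np.linalg.norm(G.matrix_to_rotvec(np.swapaxes(R0, -1, -2) @ Rt), axis=-1)
        assert ang.mean() < 0.15  # kernel width at sigma ~ 0.02

    def test_left_invariance(self, igso3_table):
        rng = np.random.default_rng(3)
        R0a = G.random_rotation(rng)
        R0b = G.random_rotation(rng)
        t = 0.4
        Rta = so3.sample_igso3(np.tile(R0a, (4000, 1, 1)), t, SCHED, igso3_table, rng)
        Rtb = so3.sample_igso3(np.tile(R0b, (4000, 1, 1)), t, SCHED, igso3_table, rng)
        wa = np.linalg.norm(G.matrix_to_rotvec(R0a.T @ Rta), axis=-1)
        wb = np.linalg.norm(G.matrix_to_rotvec(R0b.T @ Rtb), axis=-1)
        assert ks_2samp(wa, wb).pvalue > 0.01

    def test_max_sigma_samples_close_to_haar(self, igso3_table):
        rng = np.random.default_rng(9)
        R0 = G.random_rotation(rng)
        Rt = so3.sample_igso3(np.tile(R0, (10_000, 1, 1)), 1.0, SCHED, igso3_table, rng)
        w = np.linalg.norm(G.matrix_to_rotvec(np.swapaxes(Rt, -1, -2)), axis=-1)
        haar_w = np.linalg.norm(G.matrix_to_rotvec(G.random_rotation(rng, 10_000)), axis=-1)
        assert ks_2samp(w, haar_w).pvalue > 0.01


class TestScore:
    def test_score_zero_at_mode(self, igso3_table):
        rng = np.random.default_rng(0)
        R0 = G.random_rotation(rng, 5)
        s = so3.score_so3(R0, R0, 0.5, SCHED, igso3_table)
        assert np.allclose(s, 0.0)

    def test_score_antisymmetric_in_angle(self, igso3_table):
        rng = np.random.default_rng(1)
        R0 = G.random_rotation(rng)
        axis = np.array([1.0, 2.0, -0.5])
        axis /= np.linalg.norm(axis)
        w = 0.7
        Rp = R0 @ G.rotation_from_axis_angle(axis, w)
        Rm = R0 @ G.rotation_from_axis_angle(axis, -w)
        sp = so3.score_so3(Rp, R0, 0.5, SCHED, igso3_table)
        sm = so3.score_so3(Rm, R0, 0.5, SCHED, igso3_table)
        assert np.allclose(sp, -sm, atol=1e-8)

    def test_score_matches_finite_difference_of_log_density(self, igso3_table):
        sig, w, h = 0.5, 0.5, 1e-5

        def log_ftilde(x):
            return np.log(so3.igso3_density(np.array([x]), sig)[0]
                          / ((1 - np.cos(x)) / np.pi))

        fd = (log_ftilde(w + h) - log_ftilde(w - h)) / (2 * h)
        assert abs(igso3_table.dlogf(w, sig) - fd) / abs(fd) < 1e-3


class TestReverseStep:
    def test_no_drift_without_score_or_noise(self, igso3_table):
        rng = np.random.default_rng(2)
        R = G.random_rotation(rng, 6)
        out = so3.reverse_step_so3(R, np.zeros((6, 3)), 0.5, 1e-3, SCHED, rng,
                                   add_noise=False)
        assert np.allclose(out, R, atol=1e-12)

    def test_rejects_nonpositive_dt(self, igso3_table):
        rng = np.random.default_rng(2)
        R = G.random_rotation(rng, 2)
        with pytest.raises(ValueError):
            so3.reverse_step_so3(R, np.zeros((2, 3)), 0.5, 0.0, SCHED, rng)

    def test_output_stays_valid_rotation(self, igso3_table):
        rng = np.random.default_rng(3)
        R = G.random_rotation(rng, 2000)
        s = rng.normal(size=(2000, 3))
        for _ in range(5):
            R = so3.reverse_step_so3(R, s, 0.5, 1e-3, SCHED, rng)
        err = np.abs(R @ np.swapaxes(R, -1, -2) - np.eye(3)).max()
        assert err < 1e-8
        assert np.allclose(np.linalg.det(R), 1.0, atol=1e-8)

    def test_analytic_score_integration_recovers_target(self, igso3_table):
        """500-step reverse run from Haar start concentrates near the target."""
        rng = np.random.default_rng(5)
        R0 = G.random_rotation(rng, 100)
        R = G.random_rotation(rng, 100)
        n_steps = 500
        dt = 1.0 / n_steps
        for k in range(n_steps):
            t = 1.0 - k * dt
            s = so3.score_so3(R, R0, t, SCHED, igso3_table)
            R = so3.reverse_step_so3(R, s, t, dt, SCHED, rng)
        s = so3.score_so3(R, R0, 0.0, SCHED, igso3_table)
        R = so3.denoise_tweedie(R, s, float(so3.sigma(0.0, SCHED)))
        w = np.linalg.norm(G.matrix_to_rotvec(np.swapaxes(R0, -1, -2) @ R), axis=-1)
        assert w.mean() < 0.2
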