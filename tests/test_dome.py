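"""Bivariate-Gaussian dome fitting: gradient correctness, parameter
recovery on synthetic clouds, curvature formulas, 1D profiles."""

import math

import numpy as np
import pytest

from piezokit import (
    DomeModel2D,
    MembraneCloudSpec,
    curvature_series,
    fit_dome_2d,
    fit_profile_1d,
    gen_membrane_cloud,
    peak_curvatures,
)
from piezokit.dome import DomeFitError, _sse_and_grad, dome_surface


def make_cloud(dome, n=2000, box=(200, 200), noise=0.0, seed=0):
    pts, _ = gen_membrane_cloud(
        MembraneCloudSpec(dome=dome, n_points=n, box_xy=box, noise_sigma=noise, seed=seed)
    )
    return pts


@pytest.fixture()
def aniso_dome():
    return DomeModel2D(
        zo=2.0, h=-8.0, mu=np.array([5.0, -3.0]),
        sigma_p1=40.0, sigma_p2=20.0, theta_rot=math.radians(120),
    )


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self, rng):
        xy = rng.uniform(-50, 50, size=(40, 2))
        z = rng.normal(0, 3, size=40)
        params = np.array([1.0, math.log(6.0), 2.0, -1.0,
                           math.log(25.0), math.log(15.0), 0.7])
        _, grad = _sse_and_grad(params, xy, z)
        eps = 1e-6
        for j in range(7):
            p1, p2 = params.copy(), params.copy()
            p1[j] += eps
            p2[j] -= eps
            fd = (_sse_and_grad(p1, xy, z)[0] - _sse_and_grad(p2, xy, z)[0]) / (2 * eps)
            assert grad[j] == pytest.approx(fd, rel=1e-5, abs=1e-6)


class TestFitRecovery:
    def test_noise_free_identity_recovery(self, isotropic_dome):
        pts = make_cloud(isotropic_dome, n=2000, seed=11)
        m, diag = fit_dome_2d(pts)
        assert diag["converged"]
        assert m.zo == pytest.approx(0.0, abs=1e-4)
        assert m.h == pytest.approx(-8.0, rel=1e-4)
        assert m.sigma_p1 == pytest.approx(30.0, rel=1e-4)
        assert m.sigma_p2 == pytest.approx(30.0, rel=1e-4)

    def test_curvature_recovery_under_noise_20_seeds(self, isotropic_dome):
        k_true = 8.0 / 900.0
        good = 0
        for seed in range(20):
            pts = make_cloud(isotropic_dome, n=5000, noise=1.0, seed=seed)
            m, _ = fit_dome_2d(pts)
            cs = peak_curvatures(m)
            if (abs(cs.kappa1 - k_true) / k_true < 0.1
                    and abs(cs.kappa2 - k_true) / k_true < 0.1):
                good += 1
        assert good >= 18

    def test_anisotropic_orientation_recovery(self, aniso_dome):
        pts = make_cloud(aniso_dome, n=3000, box=(250, 250), seed=3)
        m, _ = fit_dome_2d(pts)
        dtheta = (m.theta_rot - aniso_dome.theta_rot) % math.pi
        assert min(dtheta, math.pi - dtheta) < 1e-3
        cs = peak_curvatures(m)
        assert cs.kappa1 < cs.kappa2  # major-axis curvature is the smaller one

    def test_kappa_bias_over_seeds(self, isotropic_dome):
        # mean bias < 3% at low noise
        k_true = 8.0 / 900.0
        ks = []
        for seed in range(50):
            pts = make_cloud(isotropic_dome, n=5000, noise=0.5, seed=100 + seed)
            cs = peak_curvatures(fit_dome_2d(pts)[0])
            ks.append(0.5 * (cs.kappa1 + cs.kappa2))
        assert abs(np.mean(ks) - k_true) / k_true < 0.03

    def test_rotational_equivariance(self, aniso_dome):
        pts = make_cloud(aniso_dome, n=3000, box=(250, 250), seed=5)
        phi = math.radians(25)
        R = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])
        rot = pts.copy()
        rot[:, :2] = pts[:, :2] @ R.T
        m0, _ = fit_dome_2d(pts)
        m1, _ = fit_dome_2d(rot)
        dtheta = (m1.theta_rot - m0.theta_rot - phi) % math.pi
        assert min(dtheta, math.pi - dtheta) < 1e-6
        c0, c1 = peak_curvatures(m0), peak_curvatures(m1)
        assert c1.kappa1 == pytest.approx(c0.kappa1, abs=1e-6)
        assert c1.kappa2 == pytest.approx(c0.kappa2, abs=1e-6)

    def test_monotone_improvement_and_spd(self, aniso_dome):
        pts = make_cloud(aniso_dome, n=1500, box=(250, 250), noise=1.0, seed=9)
        m, diag = fit_dome_2d(pts)
        assert diag["sse_final"] <= diag["sse_init"]
        C = m.C
        assert np.allclose(C, C.T)
        assert np.all(np.linalg.eigvalsh(C) > 0)
        # reconstruction identity
        th = m.theta_rot
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        C2 = R @ np.diag([m.sigma_p1**2, m.sigma_p2**2]) @ R.T
        assert np.allclose(C, C2, atol=1e-8)

    def test_degenerate_cloud_raises(self):
        line = np.column_stack([np.linspace(0, 10, 50), np.zeros(50), np.zeros(50)])
        with pytest.raises(DomeFitError):
            fit_dome_2d(line)
        with pytest.raises(ValueError):
            fit_dome_2d(np.zeros((5, 3)))


class TestPeakCurvatures:
    def test_isotropic_formula(self):
        m = DomeModel2D(zo=0, h=-5.0, mu=np.zeros(2), sigma_p1=10, sigma_p2=10,
                        theta_rot=0.0)
        cs = peak_curvatures(m)
        assert cs.kappa1 == cs.kappa2 == pytest.approx(0.05)
        assert cs.mean_curvature == pytest.approx(0.05)

    def test_anisotropic_formula(self):
        m = DomeModel2D(zo=0, h=-5.0, mu=np.zeros(2), sigma_p1=10, sigma_p2=20,
                        theta_rot=0.0)
        cs = peak_curvatures(m)
        assert (cs.kappa1, cs.kappa2) == (pytest.approx(0.05), pytest.approx(0.0125))
        assert cs.mean_curvature == pytest.approx(0.03125)

    def test_second_derivative_finite_difference_oracle(self):
        m = DomeModel2D(zo=1.0, h=-7.0, mu=np.array([2.0, -1.0]),
                        sigma_p1=25.0, sigma_p2=12.0, theta_rot=math.radians(40))
        # curvature at the peak along principal axis p1 == -d2g/ds2 / 1
        th = m.theta_rot
        for sigma, axis in [(m.sigma_p1, np.array([math.cos(th), math.sin(th)])),
                            (m.sigma_p2, np.array([-math.sin(th), math.cos(th)]))]:
            eps = 1e-3
            pts = np.array([m.mu - eps * axis, m.mu, m.mu + eps * axis])
            g = dome_surface(pts, m.zo, m.h, m.mu, m.sigma_p1, m.sigma_p2, th)
            d2 = (g[0] - 2 * g[1] + g[2]) / eps**2
            assert d2 == pytest.approx(-m.h / sigma**2, abs=1e-6)


class TestProfile1D:
    def test_noise_free_recovery(self):
        x = np.linspace(-80, 80, 400)
        z = 1.5 - 6.0 * np.exp(-((x - 4.0) ** 2) / (2 * 18.0**2))
        pts = np.column_stack([x, np.zeros_like(x), z])
        p = fit_profile_1d(pts, "xz")
        assert p.zo == pytest.approx(1.5, abs=1e-4)
        assert p.h == pytest.approx(-6.0, rel=1e-4)
        assert p.sigma == pytest.approx(18.0, rel=1e-4)
        assert p.mu == pytest.approx(4.0, abs=1e-3)

    def test_flat_membrane_zero_curvature(self):
        x = np.linspace(-50, 50, 200)
        pts = np.column_stack([x, np.zeros_like(x), np.full_like(x, 3.0)])
        p = fit_profile_1d(pts, "xz")
        assert p.curvature < 1e-6

    def test_slice_matches_2d_principal_curvature(self, isotropic_dome, rng):
        pts = make_cloud(isotropic_dome, n=50000, noise=0.5, seed=42)
        m2, _ = fit_dome_2d(pts)
        k2 = peak_curvatures(m2).kappa1
        p = fit_profile_1d(pts, "xz", axis_origin=float(m2.mu[1]), half_width=5.0)
        assert abs(p.curvature - k2) / k2 < 0.05

    def test_empty_slab_raises(self):
        pts = np.column_stack([np.zeros(50), np.full(50, 100.0), np.zeros(50)])
        with pytest.raises(DomeFitError):
            fit_profile_1d(pts, "xz", half_width=5.0)

    def test_bad_plane_tag(self):
        with pytest.raises(ValueError):
            fit_profile_1d(np.zeros((20, 3)), "xy")


class TestCurvatureSeries:
    def test_identical_frames_identical_fits(self, isotropic_dome):
        pts = make_cloud(isotropic_dome, n=1200, seed=2)
        df = curvature_series([pts] * 5)
        assert len(df) == 5
        assert df["mean_curvature"].nunique() == 1
        assert df["converged"].all()

    def test_decreasing_depth_monotone_curvature(self, isotropic_dome):
        frames = []
        for i, h in enumerate([-8.0, -6.0, -4.0, -2.0]):
            d = DomeModel2D(zo=0.0, h=h, mu=np.zeros(2), sigma_p1=30.0,
                            sigma_p2=30.0, theta_rot=0.0)
            frames.append(make_cloud(d, n=1500, seed=i))
        df = curvature_series(frames)
        assert np.all(np.diff(df["mean_curvature"]) < 0)

    def test_degenerate_frame_flagged_not_fatal(self, isotropic_dome):
        good = make_cloud(isotropic_dome, n=1200, seed=2)
        bad = np.column_stack([np.linspace(0, 1, 60), np.zeros(60), np.zeros(60)])
        df = curvature_series([good, bad, good])
        assert df["converged"].tolist() == [True, False, True]
        assert np.isnan(df.loc[1, "kappa1"])
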