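"""Scattering calculator, Guinier/Kratky/P(r) descriptors, weight fitting."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rigidflex.saxs import (GuinierError, SAXSProfile, chi_saxs,
                            debye_profile, fit_weights, guinier_rg,
                            kratky_dimensionless, pr_function, read_saxs,
                            scale_alpha, write_saxs)

Q = np.linspace(0.005, 0.30, 80)


def _sphere_cloud(n, radius, seed=0):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(int(n * 3), 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    pts *= (radius * rng.uniform(0, 1, len(pts)) ** (1 / 3))[:, None]
    return pts[:n]


class TestDebyeProfile:
    def test_single_bead_flat(self):
        prof = debye_profile(np.zeros((1, 3)), Q, form_factor=2.0)
        np.testing.assert_allclose(prof.intensity, 4.0)

    def test_two_bead_interference_zero(self):
        d = 10.0
        q = np.array([1e-6, np.pi / d])
        prof = debye_profile(np.array([[0, 0, 0], [0, 0, d]]), q)
        assert prof.intensity[0] == pytest.approx(4.0, rel=1e-9)
        assert prof.intensity[1] == pytest.approx(2.0, rel=1e-9)

    def test_forward_intensity_is_n_squared(self, rng):
        coords = rng.normal(size=(37, 3)) * 12.0
        prof = debye_profile(coords, np.array([0.0]))
        assert prof.intensity[0] == pytest.approx(37.0 ** 2, rel=1e-12)

    def test_rigid_motion_invariance(self, rng):
        coords = rng.normal(size=(25, 3)) * 10.0
        rot = Rotation.random(random_state=5).as_matrix()
        a = debye_profile(coords, Q).intensity
        b = debye_profile(coords @ rot.T + [4.0, 5.0, -6.0], Q).intensity
        np.testing.assert_allclose(a, b, rtol=1e-10)

    def test_uniform_sphere_guinier_radius(self):
        """R_g of a uniform sphere of radius R is R·sqrt(3/5)."""
        radius = 30.0
        coords = _sphere_cloud(500, radius, seed=1)
        q = np.linspace(0.001, 0.05, 100)
        prof = debye_profile(coords, q)
        rg, _ = guinier_rg(prof)
        assert rg == pytest.approx(radius * np.sqrt(3.0 / 5.0), rel=0.03)


class TestGuinier:
    def test_exact_curve_inverted(self):
        q = np.linspace(0.01, 0.03, 40)
        prof = SAXSProfile(q, 7.0 * np.exp(-(q * 40.0) ** 2 / 3.0))
        rg, i0 = guinier_rg(prof)
        assert rg == pytest.approx(40.0, abs=1e-9)
        assert i0 == pytest.approx(7.0, abs=1e-9)

    def test_noisy_curve_recovered(self, rng):
        q = np.linspace(0.015, 0.025, 50)
        ideal = 7.0 * np.exp(-(q * 40.0) ** 2 / 3.0)
        noisy = ideal * (1.0 + 0.01 * rng.normal(size=len(q)))
        rg, _ = guinier_rg(SAXSProfile(q, noisy))
        assert rg == pytest.approx(40.0, abs=1.0)

    def test_flat_profile_rejected(self):
        q = np.linspace(0.01, 0.03, 30)
        with pytest.raises(GuinierError, match="non-Guinier"):
            guinier_rg(SAXSProfile(q, np.ones_like(q)))

    def test_window_too_small(self):
        q = np.linspace(0.0, 0.3, 10)
        prof = SAXSProfile(q, np.exp(-q ** 2))
        with pytest.raises(GuinierError, match="window"):
            guinier_rg(prof, 0.015, 0.025)


class TestKratky:
    def test_zero_at_origin_and_globular_peak(self):
        rg = 40.0
        q = np.linspace(0.0, 0.1, 1001)
        prof = SAXSProfile(q, 7.0 * np.exp(-(q * rg) ** 2 / 3.0))
        x, y = kratky_dimensionless(prof, rg, 7.0)
        assert y[0] == 0.0
        # at qR_g = sqrt(3) the exact Guinier ordinate is 3/e
        idx = np.argmin(np.abs(x - np.sqrt(3.0)))
        assert y[idx] == pytest.approx(3.0 / np.e, rel=1e-3)

    def test_intensity_scale_invariance(self):
        q = np.linspace(0.0, 0.1, 50)
        i = np.exp(-(q * 30.0) ** 2 / 3.0)
        _, y1 = kratky_dimensionless(SAXSProfile(q, i), 30.0, 1.0)
        _, y2 = kratky_dimensionless(SAXSProfile(q, 5.0 * i), 30.0, 5.0)
        np.testing.assert_allclose(y1, y2, rtol=1e-12)


class TestPr:
    def test_two_bead_peak_position(self):
        d = 20.0
        q = np.linspace(0.005, 0.5, 200)
        prof = debye_profile(np.array([[0, 0, 0], [0, 0, d]]), q)
        prof = SAXSProfile(prof.q, prof.intensity,
                           0.01 * np.abs(prof.intensity) + 1e-4)
        r, p, _ = pr_function(prof, d_max=30.0, n_r=121)
        # mass near r=0 absorbs the self terms; the cross peak sits at d
        away = r > 5.0
        assert r[away][np.argmax(p[away])] == pytest.approx(d, abs=1.5)

    def test_sphere_real_space_rg_consistent(self):
        coords = _sphere_cloud(300, 25.0, seed=3)
        q = np.linspace(0.002, 0.25, 150)
        prof = debye_profile(coords, q)
        prof = SAXSProfile(prof.q, prof.intensity, 0.01 * prof.intensity)
        rg_guinier, _ = guinier_rg(prof, 0.002, 0.03)
        _, _, diag = pr_function(prof, d_max=55.0, n_r=111)
        assert diag["rg_real"] == pytest.approx(rg_guinier, rel=0.05)

    def test_normalization_and_endpoints(self):
        coords = _sphere_cloud(100, 15.0, seed=4)
        q = np.linspace(0.002, 0.3, 120)
        prof = debye_profile(coords, q)
        prof = SAXSProfile(prof.q, prof.intensity, 0.01 * prof.intensity)
        r, p, _ = pr_function(prof, d_max=35.0, normalize=True)
        assert p[0] == 0.0 and p[-1] == 0.0
        assert np.all(p >= 0.0)
        assert np.trapezoid(p, r) == pytest.approx(1.0, rel=1e-6)


class TestScaleAndChi:
    def test_identity_case_both_variants(self):
        i = np.array([3.0, 5.0, 2.0])
        assert scale_alpha(i, i, "as_printed") == pytest.approx(1.0)
        assert scale_alpha(i, i, "least_squares") == pytest.approx(1.0)

    def test_two_point_hand_case(self):
        i_exp = np.array([4.0, 2.0])
        i_avg = np.array([2.0, 1.0])
        assert scale_alpha(i_exp, i_avg, "as_printed") == pytest.approx(0.5)
        assert scale_alpha(i_exp, i_avg, "least_squares") == pytest.approx(2.0)

    def test_as_printed_homogeneity(self, rng):
        i_exp = rng.uniform(1, 5, 20)
        i_avg = rng.uniform(1, 5, 20)
        a1 = scale_alpha(i_exp, i_avg, "as_printed")
        a3 = scale_alpha(3.0 * i_exp, i_avg, "as_printed")
        assert a3 == pytest.approx(a1 / 3.0, rel=1e-12)

    def test_chi_zero_and_hand_case(self):
        i = np.array([3.0, 3.0])
        assert chi_saxs(i, np.ones(2), i, 1.0) == 0.0
        assert chi_saxs(i, np.ones(2), np.array([1.0, 1.0]), 2.0) == \
            pytest.approx(1.0)

    def test_chi_scales_inversely_with_sigma(self, rng):
        i_exp = rng.uniform(1, 5, 30)
        i_avg = rng.uniform(1, 5, 30)
        sig = rng.uniform(0.5, 2.0, 30)
        c1 = chi_saxs(i_exp, sig, i_avg, 1.3)
        c2 = chi_saxs(i_exp, 2.0 * sig, i_avg, 1.3)
        assert c2 == pytest.approx(c1 / 2.0, rel=1e-12)


class TestFitWeights:
    def _profiles(self, rng, n, nq=60):
        # conformers of varying overall size -> distinguishable profiles
        q = np.linspace(0.005, 0.3, nq)
        scales = rng.uniform(6.0, 14.0, n)
        frames = rng.normal(size=(n, 30, 3)) * scales[:, None, None]
        return np.stack([debye_profile(f, q).intensity for f in frames])

    def test_single_member_forced(self, rng):
        calc = self._profiles(rng, 1)
        fit = fit_weights(calc, calc[0], 0.01 * calc[0])
        np.testing.assert_allclose(fit.weights, [1.0])
        assert fit.chi == pytest.approx(0.0, abs=1e-6)

    def test_noiseless_mixture_recovered_exactly(self, rng):
        calc = self._profiles(rng, 2)
        i_exp = 0.6 * calc[0] + 0.4 * calc[1]
        fit = fit_weights(calc, i_exp, np.full_like(i_exp, 1.0))
        np.testing.assert_allclose(fit.weights, [0.6, 0.4], atol=1e-6)
        assert fit.chi < 1e-6

    def test_decoys_pruned_to_true_support(self, rng):
        # two well-separated true conformers (compact and expanded
        # extremes) among 50 interior decoys
        q = np.linspace(0.005, 0.3, 60)
        scales = np.concatenate([[4.0, 16.0], rng.uniform(7.0, 13.0, 50)])
        frames = rng.normal(size=(52, 30, 3)) * scales[:, None, None]
        calc = np.stack([debye_profile(f, q).intensity for f in frames])
        i_exp = 0.6 * calc[0] + 0.4 * calc[1]
        sigma = 0.01 * i_exp
        i_noisy = i_exp + rng.normal(0.0, sigma)
        fit = fit_weights(calc, i_noisy, sigma, sparsity=5)
        assert np.count_nonzero(fit.weights) <= 5
        assert fit.weights[:2].sum() >= 0.8

    def test_never_worse_than_uniform(self, rng):
        calc = self._profiles(rng, 10)
        i_exp = calc[3] * 1.7
        sigma = 0.02 * i_exp
        fit = fit_weights(calc, i_exp, sigma, sparsity=3)
        uniform = calc.mean(axis=0)
        chi_u = chi_saxs(i_exp, sigma, uniform,
                         scale_alpha(i_exp, uniform, "least_squares"))
        assert fit.chi <= chi_u + 1e-12
        assert np.all(fit.weights >= 0.0)
        assert fit.weights.sum() == pytest.approx(1.0)

    def test_grid_mismatch(self, rng):
        calc = self._profiles(rng, 3)
        with pytest.raises(ValueError, match="grid"):
            fit_weights(calc, np.ones(10), np.ones(10))


def test_profile_io_round_trip(tmp_path, rng):
    q = np.linspace(0.01, 0.3, 25)
    prof = SAXSProfile(q, rng.uniform(1, 5, 25), rng.uniform(0.1, 0.2, 25))
    p = tmp_path / "prof.dat"
    write_saxs(p, prof)
    back = read_saxs(p)
    np.testing.assert_allclose(back.q, prof.q)
    np.testing.assert_allclose(back.intensity, prof.intensity)
    np.testing.assert_allclose(back.sigma, prof.sigma)
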