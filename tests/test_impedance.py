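"""Exp3P2 and Randles impedance models and their fits."""

import math

import numpy as np
import pytest

import protospike as ps
from protospike.errors import FitFailureError

EXP_REPORTED = ps.Exp3P2Params(a=9.16432, b=-1.13394e-6, c=-5.30867e-13)
RANDLES_REPORTED = ps.RandlesParams(Rs=1.48e3, Cdl=6.95e3, Rct=9.95e4, Zw=1.23e4)


class TestExp3P2:
    def test_zero_frequency_gives_exp_a(self):
        assert ps.exp3p2(EXP_REPORTED, 0.0) == pytest.approx(math.exp(9.16432), rel=1e-14)

    def test_all_zero_parameters_give_unity(self):
        p = ps.Exp3P2Params(0.0, 0.0, 0.0)
        assert np.allclose(ps.exp3p2(p, np.array([0.0, 10.0, 1e5])), 1.0)

    def test_reported_parameters_at_high_frequency(self):
        # direct scalar evaluation of the exponent as the oracle
        f = 1e5
        expected = math.exp(9.16432 + (-1.13394e-6) * f + (-5.30867e-13) * f * f)
        assert ps.exp3p2(EXP_REPORTED, f) == pytest.approx(expected, rel=1e-14)

    def test_overflow_reported_with_frequency(self):
        with pytest.raises(OverflowError, match="1000"):
            ps.exp3p2(ps.Exp3P2Params(0.0, 1.0, 0.0), 1000.0)


class TestExp3P2Fit:
    def test_noise_free_recovery_is_machine_exact(self):
        f = np.linspace(0, 1e6, 50)
        fit = ps.fit_exp3p2(f, ps.exp3p2(EXP_REPORTED, f))
        assert fit.params.a == pytest.approx(9.16432, rel=1e-6)
        assert fit.params.b == pytest.approx(-1.13394e-6, rel=1e-6)
        assert fit.params.c == pytest.approx(-5.30867e-13, rel=1e-6)

    def test_constant_spectrum_collapses_to_intercept(self):
        f = np.linspace(0, 100, 10)
        fit = ps.fit_exp3p2(f, np.full(10, 42.0))
        assert fit.params.a == pytest.approx(math.log(42.0), abs=1e-9)
        assert fit.params.b == pytest.approx(0.0, abs=1e-12)
        assert fit.params.c == pytest.approx(0.0, abs=1e-14)

    def test_two_distinct_frequencies_rank_deficient(self):
        with pytest.raises(FitFailureError, match="rank"):
            ps.fit_exp3p2([1.0, 1.0, 2.0, 2.0], [3.0, 3.0, 4.0, 4.0])

    def test_residuals_orthogonal_to_design(self, rng):
        f = np.linspace(0, 1e4, 60)
        y = ps.exp3p2(ps.Exp3P2Params(2.0, -1e-5, 1e-11), f)
        y = y * np.exp(0.05 * rng.standard_normal(60))
        fit = ps.fit_exp3p2(f, y)
        resid = np.log(y) - (fit.params.a + fit.params.b * f + fit.params.c * f**2)
        X = np.column_stack([np.ones_like(f), f, f**2])
        # normal equations: X^T r = 0 (scaled by column norms)
        assert np.all(np.abs(X.T @ resid) / np.linalg.norm(X, axis=0) < 1e-8)


class TestRandlesModel:
    def test_purely_resistive_limit(self):
        p = ps.RandlesParams(10.0, 0.0, 90.0, 0.0)
        assert np.allclose(ps.randles_impedance(p, np.geomspace(1, 1e6, 7)), 100.0)

    def test_high_frequency_limit_is_rs(self):
        p = ps.RandlesParams(50.0, 1e-6, 1e4, 100.0)
        z = ps.randles_impedance(p, 1e9)
        assert abs(z - 50.0) < 0.1

    def test_approach_to_rs_is_monotone_above_the_knee(self):
        p = ps.RandlesParams(100.0, 1e-5, 500.0, 0.0)
        f_knee = 1 / (2 * np.pi * p.Rct * p.Cdl)
        f = np.geomspace(10 * f_knee, 1e4 * f_knee, 30)
        gap = np.abs(ps.randles_impedance(p, f) - p.Rs)
        assert np.all(np.diff(gap) < 0)

    def test_nonnegative_elements_give_nonnegative_minus_im(self):
        p = ps.RandlesParams(100.0, 1e-5, 500.0, 30.0)
        z = ps.randles_impedance(p, np.geomspace(1e-2, 1e6, 50))
        assert np.all(-z.imag >= 0)

    def test_semicircle_identity_without_diffusion(self):
        p = ps.RandlesParams(100.0, 1e-5, 500.0, 0.0)
        z = ps.randles_impedance(p, np.geomspace(1e-1, 1e6, 100))
        centre, radius = p.Rs + p.Rct / 2, p.Rct / 2
        dist = np.abs(z - centre)  # distance in the complex plane
        assert np.allclose(dist, radius, atol=1e-9 * radius)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            ps.randles_impedance(RANDLES_REPORTED, 0.0)


class TestRandlesFit:
    def test_reported_parameters_recovered_noise_free(self):
        f = np.geomspace(1e-2, 1e5, 60)
        spec = ps.generate_impedance_spectrum(RANDLES_REPORTED, f)
        init = ps.RandlesParams(*(1.3 * np.array([1.48e3, 6.95e3, 9.95e4, 1.23e4])))
        fit = ps.fit_randles(spec, init=init)
        assert fit.params.Rct == pytest.approx(9.95e4, rel=1e-3)
        assert fit.params.Rs == pytest.approx(1.48e3, rel=1e-6)
        assert fit.params.Cdl == pytest.approx(6.95e3, rel=1e-6)

    def test_refit_of_own_evaluation_residual_negligible(self):
        p = ps.RandlesParams(100.0, 1e-5, 500.0, 50.0)
        f = np.geomspace(1e-1, 1e5, 60)
        spec = ps.generate_impedance_spectrum(p, f)
        fit = ps.fit_randles(spec)
        resid = ps.randles_impedance(fit.params, f) - spec.Z
        assert np.linalg.norm(resid) < 1e-9

    def test_noisy_recovery_within_five_percent(self):
        p = ps.RandlesParams(100.0, 1e-5, 500.0, 50.0)
        spec = ps.generate_impedance_spectrum(p, np.geomspace(1e-1, 1e5, 60),
                                              noise_fraction=0.01, seed=9)
        fit = ps.fit_randles(spec, weighting="modulus")
        for name in ("Rs", "Cdl", "Rct", "Zw"):
            assert getattr(fit.params, name) == pytest.approx(getattr(p, name), rel=0.05)

    def test_too_few_points_or_narrow_span_rejected(self):
        p = ps.RandlesParams(100.0, 1e-5, 500.0, 0.0)
        f = np.geomspace(1, 10, 60)  # only one decade
        with pytest.raises(ValueError, match="decades"):
            ps.fit_randles(ps.generate_impedance_spectrum(p, f))
        f = np.geomspace(1, 1e4, 5)
        with pytest.raises(ValueError, match="8"):
            ps.fit_randles(ps.generate_impedance_spectrum(p, f))


class TestNyquist:
    def test_pointwise_transform(self):
        spec = ps.ImpedanceSpectrum([1.0, 2.0], [3 + 4j, 1 - 2j])
        assert np.array_equal(ps.nyquist(spec), [[3.0, -4.0], [1.0, 2.0]])

    def test_purely_real_spectrum_has_zero_ordinate(self):
        spec = ps.ImpedanceSpectrum([1.0, 2.0, 3.0], [5.0, 6.0, 7.0])
        assert not np.any(ps.nyquist(spec)[:, 1])

    def test_points_lie_on_the_rc_semicircle(self):
        p = ps.RandlesParams(100.0, 1e-5, 500.0, 0.0)
        spec = ps.generate_impedance_spectrum(p, np.geomspace(1e-1, 1e6, 50))
        pts = ps.nyquist(spec)
        lhs = (pts[:, 0] - (p.Rs + p.Rct / 2)) ** 2 + pts[:, 1] ** 2
        assert np.allclose(lhs, (p.Rct / 2) ** 2, rtol=1e-9)
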