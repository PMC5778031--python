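"""Spectral estimator: line positions, sum rule, OU oracle, smoothing,
segment statistics, anisotropy metrics."""

import numpy as np
import pytest

from protir.cluster_sim import generate_oscillator_dipole
from protir.dipole_defect import DipoleSeries
from protir.spectra import (
    SpectralConfig,
    Spectrum,
    average_segments,
    band_anisotropy,
    difference_spectrum,
    dipole_derivative,
    ou_lorentzian,
    radial_average,
    smooth_gaussian,
    spectrum_from_dipole,
)
from protir.units import C_CM_PER_FS

RAW = SpectralConfig(sigma_nu=0.0, nu_max=4000.0)


def ou_spectrum(seed, N=2**15, dt=0.5, sd=1.0, tau=10.0, sigma_nu=50.0):
    series, _ = generate_oscillator_dipole([], (sd, tau, "z"), N, dt, seed=seed)
    return spectrum_from_dipole(series, SpectralConfig(sigma_nu=sigma_nu, nu_max=4000.0))


class TestDerivative:
    def test_linear_ramp(self):
        t = np.arange(10.0)
        mu = np.column_stack([np.zeros(10), np.zeros(10), t])
        d = dipole_derivative(DipoleSeries(t, mu))
        np.testing.assert_allclose(d.mu[:, 2], 1.0, atol=1e-12)

    def test_constant(self):
        t = np.arange(10.0)
        d = dipole_derivative(DipoleSeries(t, np.ones((10, 3))))
        np.testing.assert_allclose(d.mu, 0.0, atol=1e-12)

    def test_cosine_taylor_bound(self):
        dt, f = 0.5, 0.02
        t = np.arange(512) * dt
        mu = np.zeros((512, 3))
        mu[:, 2] = np.cos(2 * np.pi * f * t)
        d = dipole_derivative(DipoleSeries(t, mu))
        exact = -2 * np.pi * f * np.sin(2 * np.pi * f * t)
        err = np.abs(d.mu[1:-1, 2] - exact[1:-1])
        assert err.max() <= (2 * np.pi * f) ** 3 * dt**2 / 6 * 1.01

    def test_too_short(self):
        with pytest.raises(ValueError):
            dipole_derivative(DipoleSeries(np.arange(2.0), np.zeros((2, 3))))


class TestEstimator:
    @pytest.mark.parametrize("nu0", [500.0, 1645.0, 3400.0])
    def test_line_position_recovery(self, nu0):
        series, _ = generate_oscillator_dipole(
            [(nu0, 1.0, "z", 0.3)], None, 2**14, 0.5, seed=0
        )
        sp = spectrum_from_dipole(series, RAW)
        dnu = sp.nu[1] - sp.nu[0]
        assert abs(sp.nu[np.argmax(sp.A_zz)] - nu0) <= dnu
        assert sp.A_xx.max() < 1e-12 * sp.A_zz.max()
        assert sp.A_yy.max() < 1e-12 * sp.A_zz.max()

    def test_zero_series_gives_zero_spectrum(self):
        t = np.arange(64) * 0.5
        sp = spectrum_from_dipole(DipoleSeries(t, np.zeros((64, 3))), RAW)
        assert np.all(sp.components == 0.0)

    def test_parseval_sum_rule(self):
        series, _ = generate_oscillator_dipole(
            [(1645.0, 1.0, "z", 0.0), (500.0, 0.5, "x", 1.0)], None, 4096, 0.5, seed=0
        )
        cfg = SpectralConfig(sigma_nu=0.0, nu_max=1.0 / (2 * 0.5) / C_CM_PER_FS + 1.0)
        sp = spectrum_from_dipole(series, cfg)
        dnu = sp.nu[1] - sp.nu[0]
        v = dipole_derivative(series).mu
        v = v - v.mean(axis=0)
        lhs = sp.components.sum(axis=1) * dnu
        rhs = np.mean(v**2, axis=0)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-6)

    def test_linearity_in_amplitude(self):
        s1, _ = generate_oscillator_dipole([(1000.0, 1.0, "z", 0.0)], None, 1024, 0.5)
        s3 = DipoleSeries(s1.times, 3.0 * s1.mu)
        a1 = spectrum_from_dipole(s1, RAW)
        a3 = spectrum_from_dipole(s3, RAW)
        np.testing.assert_allclose(a3.A_zz, 9.0 * a1.A_zz, rtol=1e-10, atol=1e-16)

    def test_ou_matches_lorentzian_within_10pct_rms(self):
        specs = [ou_spectrum(seed) for seed in range(8)]
        mean = average_segments(specs)
        band = (mean.nu >= 100.0) & (mean.nu <= 2000.0)
        analytic = ou_lorentzian(mean.nu[band], 1.0, 10.0)
        rel = mean.A_zz[band] / analytic - 1.0
        assert np.sqrt(np.mean(rel**2)) < 0.10

    def test_nonuniform_times_rejected(self):
        t = np.arange(64.0)
        t[10] += 0.2
        with pytest.raises(ValueError):
            spectrum_from_dipole(DipoleSeries(t, np.zeros((64, 3))), RAW)

    def test_too_few_samples_rejected(self):
        t = np.arange(8) * 0.5
        with pytest.raises(ValueError):
            spectrum_from_dipole(DipoleSeries(t, np.ones((8, 3))), RAW)


class TestSmoothing:
    def _delta_line(self, nu0=2000.0, n=2001):
        nu = np.linspace(0, 4000.0, n)
        a = np.zeros(n)
        a[np.argmin(np.abs(nu - nu0))] = 1.0
        return Spectrum(nu, a.copy(), a.copy(), a.copy())

    def test_zero_width_is_identity(self):
        sp = self._delta_line()
        out = smooth_gaussian(sp, 0.0)
        np.testing.assert_array_equal(out.components, sp.components)

    def test_delta_becomes_gaussian_of_requested_width(self):
        sp = self._delta_line()
        out = smooth_gaussian(sp, 50.0)
        w = out.A_zz / out.A_zz.sum()
        mean = np.sum(w * out.nu)
        sd = np.sqrt(np.sum(w * (out.nu - mean) ** 2))
        assert mean == pytest.approx(2000.0, abs=2.0)
        assert sd == pytest.approx(50.0, rel=0.02)

    def test_flat_input_stays_flat_and_integral_preserved(self):
        nu = np.linspace(0, 4000.0, 800)
        sp = Spectrum(nu, np.ones_like(nu), np.ones_like(nu), np.ones_like(nu))
        out = smooth_gaussian(sp, 50.0)
        np.testing.assert_allclose(out.components, 1.0, rtol=1e-9)
        sp2 = self._delta_line()
        out2 = smooth_gaussian(sp2, 50.0)
        np.testing.assert_allclose(
            out2.components.sum(axis=1), sp2.components.sum(axis=1), rtol=1e-6
        )

    def test_nonnegative_preserved(self):
        sp = self._delta_line()
        assert np.all(smooth_gaussian(sp, 120.0).components >= 0.0)


class TestSegments:
    def test_single_segment_identity(self):
        sp = ou_spectrum(0, N=1024)
        out = average_segments([sp])
        assert out.err is None and out.n_segments == 1
        np.testing.assert_array_equal(out.components, sp.components)

    def test_identical_segments_zero_error(self):
        sp = ou_spectrum(0, N=1024)
        out = average_segments([sp, sp])
        np.testing.assert_array_equal(out.components, sp.components)
        assert np.all(out.err == 0.0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            average_segments([ou_spectrum(0, N=1024), ou_spectrum(0, N=2048)])

    def test_26_segment_mean_covers_analytic_lorentzian(self):
        specs = [ou_spectrum(seed, N=4096, sigma_nu=50.0) for seed in range(26)]
        mean = average_segments(specs)
        band = (mean.nu >= 100.0) & (mean.nu <= 2000.0)
        analytic = ou_lorentzian(mean.nu[band], 1.0, 10.0)
        covered = np.abs(mean.A_zz[band] - analytic) <= 2.0 * mean.err[2][band]
        assert covered.mean() >= 0.95

    def test_equivalent_direction_error_scales_inverse_sqrt_segments(self):
        def aniso(nseg, base):
            specs = []
            for k in range(nseg):
                sx, _ = generate_oscillator_dipole([], (1.0, 10.0, "x"), 1024, 0.5, seed=base + 2 * k)
                sy, _ = generate_oscillator_dipole([], (1.0, 10.0, "y"), 1024, 0.5, seed=base + 2 * k + 1)
                specs.append(spectrum_from_dipole(
                    DipoleSeries(sx.times, sx.mu + sy.mu), SpectralConfig(sigma_nu=0.0)
                ))
            _, _, err = radial_average(average_segments(specs))
            return err.mean()

        e4, e16, e64 = aniso(4, 0), aniso(16, 1000), aniso(64, 2000)
        assert e4 / e16 == pytest.approx(2.0, rel=0.35)
        assert e16 / e64 == pytest.approx(2.0, rel=0.35)


class TestAnisotropyMetrics:
    def _spec(self, axx, ayy, azz):
        nu = np.linspace(1000.0, 3000.0, 5)
        mk = lambda v: np.full(5, float(v))
        return Spectrum(nu, mk(axx), mk(ayy), mk(azz))

    def test_radial_average_identities(self):
        z, xy, err = radial_average(self._spec(2.0, 0.0, 1.0))
        np.testing.assert_allclose(xy, 1.0)
        np.testing.assert_allclose(err, 1.0)
        z, xy, err = radial_average(self._spec(1.0, 1.0, 1.0))
        np.testing.assert_allclose(err, 0.0)

    def test_difference_of_identical_is_zero(self):
        sp = ou_spectrum(0, N=1024)
        diff = difference_spectrum(sp, sp)
        np.testing.assert_array_equal(diff.components, 0.0)

    def test_difference_grid_mismatch(self):
        with pytest.raises(ValueError):
            difference_spectrum(ou_spectrum(0, N=1024), ou_spectrum(0, N=2048))

    def test_band_ratio_isotropic_is_one(self):
        assert band_anisotropy(self._spec(1.0, 1.0, 1.0), 1200, 2800) == pytest.approx(1.0)

    def test_band_ratio_infinite_when_xy_vanishes(self):
        assert band_anisotropy(self._spec(0.0, 0.0, 1.0), 1200, 2800) == np.inf

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            band_anisotropy(self._spec(1, 1, 1), 3200, 3400)
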