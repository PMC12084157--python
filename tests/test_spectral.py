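"""Spectral core: decomposition, spectra, fits, times, kurtosis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from activeflicker import spectral as sp
from activeflicker import synthetic as syn
from activeflicker.containers import ContourSeries, SpectrumResult, phi_grid
from activeflicker.params import MembraneParams


def brute_force_quadrature(radii, phi, q):
    """Trapezoidal a_q, b_q integrals written out independently."""
    phi_c = np.concatenate([phi, [phi[0] + 2 * np.pi]])
    r_c = np.concatenate([radii, radii[:1]])
    a = np.trapezoid(r_c * np.sin(q * phi_c), phi_c) / np.pi
    b = np.trapezoid(r_c * np.cos(q * phi_c), phi_c) / np.pi
    return a, b


@st.composite
def band_limited_contours(draw):
    q_max = draw(st.integers(2, 12))
    rng = np.random.default_rng(draw(st.integers(0, 2**31 - 1)))
    amps = 0.02 * rng.standard_normal(q_max - 1)
    phases = rng.uniform(0, 2 * np.pi, q_max - 1)
    phi = phi_grid(360)
    r = 20.0 * (1 + sum(a * np.cos(q * phi + p)
                        for q, a, p in zip(range(2, q_max + 1), amps, phases)))
    return phi, r, q_max


class TestDecomposition:
    def test_circle_has_no_modes(self):
        phi = phi_grid()
        m = sp.decompose_contour(np.full((1, 360), 7.0), q_max=10, phi=phi)
        assert np.all(np.abs(m.coefficients) < 1e-12)

    def test_half_amplitude_convention(self):
        """R = R0 (1 + 0.1 cos 3phi) carries |u_3| = 0.05 and nothing else."""
        phi = phi_grid()
        r = 20.0 * (1 + 0.1 * np.cos(3 * phi))
        m = sp.decompose_contour(r[None, :], q_max=10, phi=phi)
        assert abs(m.mode(3)[0]) == pytest.approx(0.05, abs=1e-12)
        others = [abs(m.mode(q)[0]) for q in range(1, 11) if q != 3]
        assert max(others) < 1e-6

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(band_limited_contours())
    def test_quadrature_matches_brute_force_and_round_trips(self, contour):
        phi, r, q_max = contour
        series = ContourSeries(phi=phi, radii=r[None, :], dt=1.0)
        m = sp.decompose_contour(series, q_max=q_max)
        R0 = series.R0
        for q in range(1, q_max + 1):
            a, b = brute_force_quadrature(r, phi, q)
            u_expect = (b - 1j * a) / (2 * R0)
            assert m.mode(q)[0] == pytest.approx(u_expect, rel=1e-10, abs=1e-14)
        rec = sp.reconstruct_contour(m, phi)
        assert np.max(np.abs(rec[0] - r)) < 1e-3 * R0

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(band_limited_contours())
    def test_parseval_consistency(self, contour):
        """Angular variance of dR/R0 equals 2 sum_q |u_q|^2 within 1%."""
        phi, r, q_max = contour
        m = sp.decompose_contour(r[None, :], q_max=q_max + 2, phi=phi)
        var_real = np.var(r / np.mean(r) - 1.0)
        var_modes = 2 * np.sum(np.abs(m.coefficients[0]) ** 2)
        assert var_modes == pytest.approx(var_real, rel=0.01, abs=1e-14)

    def test_too_few_samples_rejected(self):
        phi = phi_grid(20)
        with pytest.raises(ValueError, match="angular samples"):
            sp.decompose_contour(np.ones((1, 20)), q_max=15, phi=phi)

    def test_nonuniform_grid_rejected(self):
        phi = np.sort(np.random.default_rng(0).uniform(0, 2 * np.pi, 100))
        with pytest.raises(ValueError, match="uniform"):
            sp.decompose_contour(np.ones((1, 100)), q_max=5, phi=phi)


class TestSpectrum:
    def test_white_noise_matches_sample_variance(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal((500, 4)) + 1j * rng.standard_normal((500, 4))
        from activeflicker.containers import ModeTrajectory

        mt = ModeTrajectory(q_values=np.arange(1, 5), coefficients=u, dt=1.0)
        spec = sp.fluctuation_spectrum(mt)
        du = u - u.mean(axis=0)
        assert np.allclose(spec.power, np.mean(np.abs(du) ** 2, axis=0))

    def test_constant_contour_zero_spectrum(self):
        from activeflicker.containers import ModeTrajectory

        u = np.full((200, 3), 0.1 + 0.1j)
        mt = ModeTrajectory(q_values=np.arange(1, 4), coefficients=u, dt=1.0)
        spec = sp.fluctuation_spectrum(mt)
        assert np.allclose(spec.power, 0.0)

    def test_sem_undefined_with_few_blocks(self):
        from activeflicker.containers import ModeTrajectory

        rng = np.random.default_rng(1)
        u = rng.standard_normal((120, 2)) * (1 + 0j)
        mt = ModeTrajectory(q_values=np.arange(1, 3), coefficients=u, dt=1.0)
        spec = sp.fluctuation_spectrum(mt, n_blocks=2)
        assert np.all(np.isnan(spec.sem))


class TestHelfrichFit:
    def test_noiseless_inversion_recovers_exactly(self):
        qs = np.arange(1, 16)
        p = MembraneParams(kappa=17.3, sigma=2.1e-8, R0=25.0)
        power = p.mode_variance(qs)
        spec = SpectrumResult(q_values=qs, power=power, sem=0.01 * power,
                              n_frames=1000)
        fit = sp.fit_helfrich(spec, R0=25.0, fit_range=(2, 15))
        assert fit.kappa_hat == pytest.approx(17.3, rel=1e-6)
        assert fit.sigma_bar_hat == pytest.approx(p.sigma_bar, rel=1e-5)
        assert fit.sigma_hat == pytest.approx(2.1e-8, rel=1e-4)

    def test_estimator_bias_and_coverage(self):
        """Over 20 passive seeds the mean kappa_hat is within 5% of
        truth and the 1-sigma CI covers truth at a sane rate."""
        p = MembraneParams(kappa=13.4, sigma=0.0, R0=25.0)
        hats, errs = [], []
        for seed in range(20):
            mt = syn.simulate_passive_modes(p, n_modes=15, dt=0.2,
                                            n_steps=5000, seed=seed)
            spec = sp.fluctuation_spectrum(mt)
            fit = sp.fit_helfrich(spec, R0=25.0, fit_range=(3, 15))
            hats.append(fit.kappa_hat)
            errs.append(fit.kappa_err)
        hats = np.array(hats)
        assert abs(hats.mean() - 13.4) / 13.4 < 0.05
        cover = np.mean(np.abs(hats - 13.4) < 2 * np.array(errs))
        assert cover >= 0.8

    def test_nonpositive_entries_rejected(self):
        qs = np.arange(1, 10)
        spec = SpectrumResult(q_values=qs, power=np.zeros(9),
                              sem=np.ones(9), n_frames=100)
        with pytest.raises(ValueError, match="non-positive"):
            sp.fit_helfrich(spec, R0=25.0)

    def test_zero_tension_reported_below_resolution(self):
        qs = np.arange(2, 16)
        p = MembraneParams(kappa=13.4, sigma=0.0, R0=25.0)
        power = p.mode_variance(qs)
        spec = SpectrumResult(q_values=qs, power=power, sem=0.01 * power,
                              n_frames=1000)
        fit = sp.fit_helfrich(spec, R0=25.0)
        assert fit.tension_below_resolution

    def test_equatorial_3d_model_prefactor(self):
        """The quasi-spherical equatorial spectrum is ~an order of
        magnitude below the 2D ring form at equal kappa and keeps the
        q^-3 scaling."""
        qs = np.arange(2, 13)
        p3d = sp.equatorial_power_quasispherical(qs, kappa=20.0, sigma_bar=0.0)
        ring = 0.5 / (20.0 * qs.astype(float) ** 3)
        ratio = p3d / ring
        assert np.all((ratio > 0.05) & (ratio < 0.15))
        slope, _ = sp.fit_powerlaw(qs, p3d, (3, 12))
        assert abs(slope) == pytest.approx(3.0, abs=0.15)

    def test_equatorial_3d_fit_inverts_its_model(self):
        qs = np.arange(2, 13)
        power = sp.equatorial_power_quasispherical(qs, kappa=23.0, sigma_bar=7.0)
        spec = SpectrumResult(q_values=qs, power=power, sem=0.01 * power,
                              n_frames=500)
        fit = sp.fit_helfrich_equatorial(spec, R0=20.0, fit_range=(2, 12))
        assert fit.kappa_hat == pytest.approx(23.0, rel=1e-4)
        assert fit.sigma_bar_hat == pytest.approx(7.0, rel=1e-3)


class TestPowerLaw:
    def test_exact_cubic(self):
        q = np.arange(2, 12)
        slope, err = sp.fit_powerlaw(q, q.astype(float) ** -3)
        assert slope == pytest.approx(-3.0, abs=1e-12)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(3)
        q = np.arange(2, 15).astype(float)
        y = 4.2 / q * np.exp(0.05 * rng.standard_normal(q.size))
        slope, err = sp.fit_powerlaw(q, y)
        assert slope == pytest.approx(-1.0, abs=0.1)
        assert err > 0

    def test_two_points_error_undefined(self):
        slope, err = sp.fit_powerlaw([1.0, 2.0], [1.0, 0.5])
        assert np.isnan(err)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            sp.fit_powerlaw([1, 2, 3], [1.0, -1.0, 0.5])


class TestCorrelationTimes:
    def test_ou_oracle(self):
        """OU with tau = 2 s estimated within 10% from 1e4 s of data."""
        rng = np.random.default_rng(5)
        dt, tau, n = 0.1, 2.0, 100000
        rho = np.exp(-dt / tau)
        innov = rng.standard_normal((n, 2)) * np.sqrt(1 - rho**2)
        from scipy.signal import lfilter

        x = lfilter([1], [1, -rho], innov[:, 0]) + \
            1j * lfilter([1], [1, -rho], innov[:, 1])
        from activeflicker.containers import ModeTrajectory

        mt = ModeTrajectory(q_values=[2], coefficients=x[:, None], dt=dt)
        ct = sp.correlation_times(mt)
        assert 1.8 <= ct.tau[0] <= 2.2

    def test_rigid_rotation_analytic(self):
        t = np.arange(20000) * 0.1
        omega = 0.04
        from activeflicker.containers import ModeTrajectory

        u = np.stack([np.exp(-1j * q * omega * t) for q in (2, 5)], axis=1)
        mt = ModeTrajectory(q_values=[2, 5], coefficients=u, dt=0.1)
        ct = sp.correlation_times(mt)
        for i, q in enumerate((2, 5)):
            expected = np.arccos(1 / np.e) / (q * omega)
            assert ct.tau[i] == pytest.approx(expected, rel=0.05)

    def test_white_noise_resolution_limited(self):
        rng = np.random.default_rng(6)
        u = rng.standard_normal((5000, 1)) * (1 + 0j)
        from activeflicker.containers import ModeTrajectory

        mt = ModeTrajectory(q_values=[3], coefficients=u, dt=0.5)
        ct = sp.correlation_times(mt)
        assert ct.tau[0] <= 0.5  # at or below one frame: resolution-limited

    def test_no_crossing_flagged(self):
        from activeflicker.containers import ModeTrajectory

        u = (np.ones(1000) + 0.001 * np.arange(1000)) * (1 + 0j)
        mt = ModeTrajectory(q_values=[2], coefficients=u[:, None], dt=1.0)
        ct = sp.correlation_times(mt, max_lag_frac=0.1)
        assert np.isnan(ct.tau[0])


class TestKurtosis:
    def test_uniform_oracle(self):
        """Uniform deformations have excess kurtosis -6/5 exactly."""
        rng = np.random.default_rng(7)
        phi = phi_grid(100)
        radii = 20.0 + rng.uniform(-1, 1, (4000, 100))
        c = ContourSeries(phi=phi, radii=radii, dt=0.1)
        res = sp.kurtosis_analysis(c, [5.0, 20.0])
        assert np.all(np.abs(res.mean - (-1.2)) < 0.1)

    def test_gaussian_passive_is_mesokurtic(self, passive_record):
        res = sp.kurtosis_analysis(passive_record.contour, [2.0, 5.0, 10.0])
        assert res.tau_avg_values.size == 3
        assert np.all(np.abs(res.mean) < 0.2)

    def test_active_intermittency_decays_with_window(self):
        """|excess kurtosis| is larger at short averaging windows than
        near the configuration decorrelation time, echoing the active
        GUV trend."""
        k_short, k_long = [], []
        for seed in range(4):
            rec = syn.active_preset(seed=seed, n_steps=3000, dt=0.2)
            res = sp.kurtosis_analysis(rec.contour, [2.0, 10.0],
                                       min_window_samples=10)
            k_short.append(abs(res.mean[0]))
            k_long.append(abs(res.mean[1]))
        assert np.mean(k_short) > np.mean(k_long)

    def test_short_window_skipped_with_warning(self, passive_record):
        with pytest.warns(UserWarning, match="skipped"):
            res = sp.kurtosis_analysis(passive_record.contour, [0.5, 10.0])
        assert res.tau_avg_values.tolist() == [10.0]


class TestDensityModes:
    def test_normalized_at_q2(self, active_record):
        spec, times, _ = sp.density_spectrum_and_times(active_record.density)
        assert spec.power[1] == pytest.approx(1.0)

    def test_density_times_track_membrane(self, active_record):
        """One advection process moves both fields, so tau_q^MT matches
        the membrane tau_q within 30% for q = 2..8."""
        _, times_d, _ = sp.density_spectrum_and_times(active_record.density)
        modes = sp.decompose_contour(active_record.contour)
        ct_m = sp.correlation_times(modes)
        for q in range(2, 9):
            ratio = ct_m.tau[q - 1] / times_d.tau[q - 1]
            assert 0.7 < ratio < 1.3

    def test_static_density_flagged(self):
        from activeflicker.containers import DensityField

        phi = phi_grid(60)
        rho = np.tile(1.0 + np.cos(phi), (300, 1))
        d = DensityField(phi=phi, rho=rho, dt=0.1)
        spec, times, _ = sp.density_spectrum_and_times(d, q_max=5,
                                                       normalize_at_q2=False)
        assert np.all(np.isnan(times.tau) | (times.tau <= 0.1))
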