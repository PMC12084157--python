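"""Rendering + contour/density/flow extraction round-trips."""

import numpy as np
import pytest

from activeflicker import extract as ex
from activeflicker import spectral as sp
from activeflicker import synthetic as syn
from activeflicker.containers import (
    ContourSeries,
    DensityField,
    SyntheticRecord,
    phi_grid,
)
from activeflicker.params import ActiveNoiseParams, MembraneParams
from activeflicker.render import render_frames


def _record_from_radii(radii, dt=0.2, density=None):
    phi = phi_grid()
    contour = ContourSeries(phi=phi, radii=np.atleast_2d(radii), dt=dt)
    dens = None
    if density is not None:
        dens = DensityField(phi=phi, rho=np.atleast_2d(density), dt=dt)
    modes = sp.decompose_contour(contour)
    return SyntheticRecord(contour=contour, density=dens, mode_truth=modes,
                           membrane=None)


@pytest.fixture(scope="module")
def circle_render():
    rec = _record_from_radii(np.full(360, 20.0))
    return render_frames(rec, noise_model="none")


CFG = ex.ExtractionConfig()


class TestRendering:
    def test_determinism(self):
        rec = syn.active_preset(seed=2, n_steps=5, dt=0.2)
        a = render_frames(rec, seed=9, image_shape=(320, 320))
        b = render_frames(rec, seed=9, image_shape=(320, 320))
        assert np.array_equal(a.membrane, b.membrane)
        assert np.array_equal(a.mt, b.mt)

    def test_vesicle_exceeding_frame_rejected(self):
        rec = _record_from_radii(np.full(360, 40.0))
        with pytest.raises(ValueError, match="exceeds"):
            render_frames(rec, image_shape=(128, 128))


class TestFindCenter:
    def test_centred_circle(self, circle_render):
        cx, cy = ex.find_center(circle_render.membrane[0])
        assert abs(cx - 127.5) < 0.5 and abs(cy - 127.5) < 0.5

    def test_uniform_frame_errors(self):
        with pytest.raises(ex.EmptyFrameError):
            ex.find_center(np.ones((64, 64)))

    def test_off_centre_ellipse(self):
        phi = phi_grid()
        r = 15.0 * (1 + 0.08 * np.cos(2 * phi))
        rec = _record_from_radii(r)
        rr = render_frames(rec, noise_model="none")
        img = np.roll(np.roll(rr.membrane[0], 8, axis=0), -5, axis=1)
        cx, cy = ex.find_center(img)
        assert abs(cx - (127.5 - 5)) < 1.0
        assert abs(cy - (127.5 + 8)) < 1.0


class TestExtractContour:
    def test_circle_within_one_pixel(self, circle_render):
        c = ex.find_center(circle_render.membrane[0])
        _, radii, miss = ex.extract_contour(circle_render.membrane[0], c, CFG)
        assert miss == 0
        assert np.max(np.abs(radii - 20.0)) <= CFG.pixel_size

    def test_mode3_amplitude_within_5pct(self):
        phi = phi_grid()
        rec = _record_from_radii(20.0 * (1 + 0.1 * np.cos(3 * phi)))
        rr = render_frames(rec, noise_model="none")
        c = ex.find_center(rr.membrane[0])
        p, radii, _ = ex.extract_contour(rr.membrane[0], c, CFG)
        m = sp.decompose_contour(ContourSeries(phi=p, radii=radii[None, :],
                                               dt=1.0))
        assert abs(m.mode(3)[0]) == pytest.approx(0.05, rel=0.05)

    def test_displaced_center_absorbed_by_q1(self, circle_render):
        """A centre offset appears as a q = 1 mode; re-centring recovers
        the true contour within a pixel."""
        frame = circle_render.membrane[0]
        delta_um = 2.0 * CFG.pixel_size  # centre displaced +2 px along x
        p, radii, _ = ex.extract_contour(frame, (127.5 + 2.0, 127.5), CFG)
        m = sp.decompose_contour(ContourSeries(phi=p, radii=radii[None, :],
                                               dt=1.0))
        # R(phi) ~ R0 - delta cos(phi)  ->  Re u_1 = -delta / (2 R0)
        delta_est = -2.0 * np.real(m.mode(1)[0]) * m.R0
        assert delta_est == pytest.approx(delta_um, abs=0.1)
        # with q=1 removed, the contour is the true circle again
        m.coefficients[0, 0] = 0.0
        rec = sp.reconstruct_contour(m, p)
        assert np.max(np.abs(rec[0] - 20.0)) <= CFG.pixel_size

    def test_rotation_equivariance(self):
        """Rotating the frame by 90 deg rotates R(phi) by pi/2."""
        phi = phi_grid()
        rec = _record_from_radii(18.0 * (1 + 0.06 * np.cos(3 * phi)
                                         + 0.03 * np.sin(5 * phi)))
        rr = render_frames(rec, noise_model="none")
        f0 = rr.membrane[0]
        f90 = np.rot90(f0)  # CCW rotation about the image centre
        _, r0, _ = ex.extract_contour(f0, (127.5, 127.5), CFG)
        _, r90, _ = ex.extract_contour(f90, (127.5, 127.5), CFG)
        # np.rot90 on [y, x] maps phi -> phi - 90deg in the math convention
        assert np.allclose(np.roll(r0, -90), r90, atol=0.05)

    def test_flat_frame_rejected(self):
        with pytest.raises(ex.FrameRejectedError):
            ex.extract_contour(np.zeros((128, 128)), (64.0, 64.0), CFG)


class TestExtractDensity:
    def test_round_trip_correlation(self):
        phi = phi_grid()
        rho = 0.2 + 0.8 * np.exp(-((np.angle(np.exp(1j * (phi - 2.0)))) ** 2)
                                 / (2 * 0.3**2))
        rec = _record_from_radii(np.full(360, 20.0), density=rho)
        rr = render_frames(rec, noise_model="none")
        c = ex.find_center(rr.membrane[0])
        _, radii, _ = ex.extract_contour(rr.membrane[0], c, CFG)
        rho_hat = ex.extract_density(rr.mt[0], radii, c, CFG)
        cc = np.corrcoef(rho_hat, rho)[0, 1]
        assert cc > 0.95

    def test_single_bump_located(self):
        phi = phi_grid()
        phi0 = 4.1
        rho = np.exp(-((np.angle(np.exp(1j * (phi - phi0)))) ** 2)
                     / (2 * 0.25**2))
        rec = _record_from_radii(np.full(360, 20.0), density=rho)
        rr = render_frames(rec, noise_model="none")
        c = ex.find_center(rr.membrane[0])
        _, radii, _ = ex.extract_contour(rr.membrane[0], c, CFG)
        rho_hat = ex.extract_density(rr.mt[0], radii, c, CFG)
        lag = np.angle(np.exp(1j * (phi[np.argmax(rho_hat)] - phi0)))
        assert abs(lag) <= 2 * np.pi / 360 + CFG.segment_spacing_dphi

    def test_zero_channel_is_background(self):
        rec = _record_from_radii(np.full(360, 20.0),
                                 density=np.zeros(360))
        rr = render_frames(rec, noise_model="none")
        c = ex.find_center(rr.membrane[0])
        _, radii, _ = ex.extract_contour(rr.membrane[0], c, CFG)
        rho_hat = ex.extract_density(rr.mt[0], radii, c, CFG)
        assert np.max(np.abs(rho_hat)) < 1.0  # counts, before normalization


class TestRadialProfile:
    def test_band_profile_peaks_at_membrane(self):
        phi = phi_grid()
        rho = np.full(360, 1.0)
        rec = _record_from_radii(np.tile(np.full(360, 20.0), (12, 1)),
                                 density=np.tile(rho, (12, 1)))
        rr = render_frames(rec, noise_model="none")
        contours = ContourSeries(phi=phi, radii=rec.contour.radii, dt=0.2)
        prof = ex.radial_density_profile(rr.mt, contours, (127.5, 127.5), CFG)
        peak_r = prof[np.argmax(prof[:, 1]), 0]
        assert 0.85 <= peak_r <= 1.0

    def test_empty_channel_flat(self):
        phi = phi_grid()
        contours = ContourSeries(phi=phi,
                                 radii=np.tile(np.full(360, 20.0), (12, 1)),
                                 dt=0.2)
        stack = np.zeros((12, 256, 256))
        prof = ex.radial_density_profile(stack, contours, (127.5, 127.5), CFG)
        assert np.allclose(prof[:, 1], 0.0)

    def test_too_few_frames(self):
        phi = phi_grid()
        contours = ContourSeries(phi=phi, radii=np.full((3, 360), 20.0), dt=0.2)
        with pytest.raises(ValueError, match="frames"):
            ex.radial_density_profile(np.zeros((3, 64, 64)), contours,
                                      (32, 32), CFG)


class TestFlow:
    @staticmethod
    def _advected_density(omega, n=300, dt=0.2, phi0=1.0, width=0.3):
        phi = phi_grid()
        t = np.arange(n) * dt
        d = np.angle(np.exp(1j * (phi[None, :] - phi0 - omega * t[:, None])))
        rho = np.exp(-d**2 / (2 * width**2))
        contours = ContourSeries(phi=phi, radii=np.full((n, 360), 20.0), dt=dt)
        return DensityField(phi=phi, rho=rho, dt=dt), contours

    def test_rotating_bump_speed_and_sign(self):
        omega = 0.05  # rad/s CCW
        dens, cont = self._advected_density(omega)
        flow = ex.compute_flow(dens, cont, window=4.0)
        sector = int(1.0 / (2 * np.pi / 36))  # sector containing the bump
        v = np.nanmean(flow.v_tangential[:, sector - 1:sector + 2])
        assert v == pytest.approx(omega * 20.0, rel=0.10)
        assert v > 0

    def test_static_density_zero_flow(self):
        dens, cont = self._advected_density(0.0)
        flow = ex.compute_flow(dens, cont, window=4.0)
        assert np.nanmax(np.abs(flow.v_tangential)) < 0.05

    def test_counter_rotating_bumps_opposite_signs(self):
        phi = phi_grid()
        n, dt = 300, 0.2
        t = np.arange(n) * dt
        d1 = np.angle(np.exp(1j * (phi[None, :] - 0.8 - 0.05 * t[:, None])))
        d2 = np.angle(np.exp(1j * (phi[None, :] - 4.0 + 0.05 * t[:, None])))
        rho = np.exp(-d1**2 / 0.1) + np.exp(-d2**2 / 0.1)
        dens = DensityField(phi=phi, rho=rho, dt=dt)
        cont = ContourSeries(phi=phi, radii=np.full((n, 360), 20.0), dt=dt)
        flow = ex.compute_flow(dens, cont, window=4.0)
        s1 = int(0.8 / (2 * np.pi / 36))
        s2 = int(4.0 / (2 * np.pi / 36))
        assert np.nanmean(flow.v_tangential[:, s1]) > 0
        assert np.nanmean(flow.v_tangential[:, s2]) < 0


class TestDensityDeformationCorrelation:
    def test_proportional_fields_correlate_perfectly(self):
        phi = phi_grid()
        rng = np.random.default_rng(2)
        defo = 0.05 * rng.standard_normal((50, 360))
        radii = 20.0 * (1 + defo)
        cont = ContourSeries(phi=phi, radii=radii, dt=0.2)
        rho = (radii - cont.R0) / cont.R0  # exactly proportional
        dens = DensityField(phi=phi, rho=rho - rho.min(), dt=0.2)
        r, lags, xc = ex.density_deformation_correlation(cont, dens)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_independent_fields_uncorrelated(self):
        phi = phi_grid()
        rng = np.random.default_rng(3)
        cont = ContourSeries(phi=phi,
                             radii=20 + rng.standard_normal((30, 360)), dt=0.2)
        dens = DensityField(phi=phi, rho=rng.standard_normal((30, 360)), dt=0.2)
        r, _, _ = ex.density_deformation_correlation(cont, dens)
        assert abs(r) < 0.05

    def test_constant_series_undefined(self):
        phi = phi_grid()
        cont = ContourSeries(phi=phi, radii=np.full((10, 360), 20.0), dt=0.2)
        dens = DensityField(phi=phi, rho=np.ones((10, 360)), dt=0.2)
        r, _, _ = ex.density_deformation_correlation(cont, dens)
        assert np.isnan(r)


class TestEndToEnd:
    def test_spectrum_round_trip_high_snr(self):
        """Render -> extract -> spectrum recovers the generator's
        per-mode power within 10% for q <= 10."""
        rec = syn.active_preset(seed=1, n_steps=250, dt=0.2)
        rr = render_frames(rec, seed=5, image_shape=(320, 320))
        cont, _, n_rej = ex.extract_stack(rr.membrane, CFG, dt=0.2)
        assert n_rej == 0
        truth = sp.fluctuation_spectrum(rec.mode_truth, n_blocks=10)
        est = sp.fluctuation_spectrum(sp.decompose_contour(cont), n_blocks=10)
        for q in range(2, 11):
            ratio = est.power[q - 1] / truth.power[q - 1]
            assert 0.9 < ratio < 1.1, f"mode {q} ratio {ratio:.2f}"
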