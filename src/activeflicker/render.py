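"""Render synthetic records into two-channel equatorial image stacks.

Channel 0 draws the membrane as a bright closed curve at R(phi, t) with a
Gaussian radial profile of width ``psf_sigma_um``; channel 1 draws the
angular density as intensity concentrated in the band [R - dR, R].
Pixel grid convention: images indexed [row, col] = [y, x], origin at the
image corner, x = col * pixel_size; the vesicle centre is returned in the
metadata in pixel units (x, y).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import SyntheticRecord


@dataclass
class RenderResult:
    membrane: np.ndarray  # (n_frames, ny, nx) float
    mt: np.ndarray | None  # (n_frames, ny, nx) or None
    pixel_size: float  # um
    center_px: tuple  # (x, y) in pixels
    psf_sigma_um: float
    dt: float


def _interp_periodic(phi_grid: np.ndarray, values: np.ndarray,
                     phi_query: np.ndarray) -> np.ndarray:
    """Periodic linear interpolation of an angular profile."""
    m = phi_grid.size
    ext_phi = np.concatenate([phi_grid, [phi_grid[0] + 2 * np.pi]])
    ext_val = np.concatenate([values, values[:1]])
    return np.interp(np.mod(phi_query, 2 * np.pi), ext_phi, ext_val)


def render_frames(record: SyntheticRecord, pixel_size_um: float = 0.25,
                  image_shape: tuple = (256, 256), psf_sigma_um: float = 0.4,
                  noise_model: str = "poisson-gaussian", seed: int = 0,
                  peak_counts: float = 400.0, read_noise: float = 2.0,
                  density_dR_um: float = 5.0,
                  background_counts: float = 10.0) -> RenderResult:
    """Draw the record's contour and density into image stacks.

    ``noise_model`` is "poisson-gaussian" (shot noise on the expected
    counts plus Gaussian read noise) or "none" (noiseless expected
    intensity).  ``peak_counts`` sets the membrane-ring peak in photon
    counts; the default SNR ~ sqrt(400) = 20 puts extraction accuracy,
    not denoising, under test.  The vesicle must fit inside the frame
    with a margin of at least 3 psf widths.
    """
    contour = record.contour
    ny, nx = image_shape
    cx = nx / 2.0 * pixel_size_um
    cy = ny / 2.0 * pixel_size_um
    r_max = float(np.max(contour.radii))
    margin = 3.0 * psf_sigma_um
    if (r_max + margin > cx or r_max + margin > cy):
        raise ValueError(
            f"vesicle (max R={r_max:.1f} um + margin) exceeds the "
            f"{ny}x{nx} frame at {pixel_size_um} um/px")

    x = (np.arange(nx) + 0.5) * pixel_size_um - cx
    y = (np.arange(ny) + 0.5) * pixel_size_um - cy
    X, Y = np.meshgrid(x, y)
    r_p = np.hypot(X, Y)
    phi_p = np.mod(np.arctan2(Y, X), 2 * np.pi)

    rng = np.random.default_rng(seed)
    n_frames = contour.n_frames
    mem = np.empty((n_frames, ny, nx), dtype=np.float32)
    has_density = record.density is not None
    mt = np.empty((n_frames, ny, nx), dtype=np.float32) if has_density else None
    inv2s2 = 1.0 / (2.0 * psf_sigma_um**2)
    edge = max(psf_sigma_um, pixel_size_um)
    for k in range(n_frames):
        Rk = _interp_periodic(contour.phi, contour.radii[k], phi_p.ravel())
        Rk = Rk.reshape(phi_p.shape)
        img = peak_counts * np.exp(-((r_p - Rk) ** 2) * inv2s2) + background_counts
        if noise_model == "poisson-gaussian":
            img = rng.poisson(img).astype(np.float32)
            img += rng.normal(0.0, read_noise, img.shape).astype(np.float32)
        elif noise_model != "none":
            raise ValueError(f"unknown noise_model {noise_model!r}")
        mem[k] = img
        if has_density:
            rho_k = _interp_periodic(record.density.phi, record.density.rho[k],
                                     phi_p.ravel()).reshape(phi_p.shape)
            band = (_smoothstep((r_p - (Rk - density_dR_um)) / edge)
                    * _smoothstep((Rk - r_p) / edge))
            # microtubules accumulate against the membrane: ramp the band
            # intensity up towards R(phi)
            with np.errstate(invalid="ignore"):
                ramp = 0.3 + 0.7 * np.clip(
                    1.0 - (Rk - r_p) / density_dR_um, 0.0, 1.0)
            band = band * ramp
            dimg = peak_counts * rho_k * band + background_counts
            if noise_model == "poisson-gaussian":
                dimg = rng.poisson(np.maximum(dimg, 0.0)).astype(np.float32)
                dimg += rng.normal(0.0, read_noise, dimg.shape).astype(np.float32)
            mt[k] = dimg
    return RenderResult(membrane=mem, mt=mt, pixel_size=pixel_size_um,
                        center_px=(nx / 2.0, ny / 2.0),
                        psf_sigma_um=psf_sigma_um, dt=contour.dt)


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)
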