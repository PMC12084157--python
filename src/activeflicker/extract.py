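"""Contour, density and flow extraction from equatorial image stacks.

The angular-segment procedure: space around the vesicle centre is divided
into overlapping segments of amplitude ``da`` (default 0.25 rad) spaced by
``dphi`` (default 0.15 rad); within each segment the radius of the
maximum-intensity point of the membrane channel is found, refined to
subpixel precision by a 3-point parabolic fit along the radial profile.
Microtubule density is the mean MT-channel intensity in a box between
R(phi) - dR and R(phi) (default dR = 5 um), background-subtracted.

Units: pixels at the image boundary, micrometres and seconds beyond it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .containers import ContourSeries, DensityField, FlowField, M_PHI, phi_grid


class EmptyFrameError(ValueError):
    """No signal above threshold in a frame."""


class FrameRejectedError(ValueError):
    """Too many missing contour samples in a frame."""


@dataclass(frozen=True)
class ExtractionConfig:
    """Parameters of the angular-segment extraction."""

    segment_amplitude_da: float = 0.25  # rad
    segment_spacing_dphi: float = 0.15  # rad
    density_box_dR: float = 5.0  # um
    center_mode: str = "per-frame"  # or "fixed"
    pixel_size: float = 0.25  # um
    max_missing_fraction: float = 0.10
    background_offset_um: float = 2.0  # background ring starts at R + this

    def __post_init__(self) -> None:
        if not (0 < self.segment_spacing_dphi <= self.segment_amplitude_da):
            raise ValueError("require 0 < dphi <= da")
        if self.density_box_dR <= 0:
            raise ValueError("dR must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


def _segment_angles(config: ExtractionConfig):
    n_seg = int(np.ceil(2 * np.pi / config.segment_spacing_dphi))
    return np.arange(n_seg) * (2 * np.pi / n_seg)


def _polar_profiles(frame: np.ndarray, center: tuple, config: ExtractionConfig,
                    r_grid: np.ndarray, seg_centers: np.ndarray,
                    n_sub: int = 9) -> np.ndarray:
    """Mean radial intensity profile per angular segment, (n_seg, n_r)."""
    da = config.segment_amplitude_da
    offs = (np.arange(n_sub) - (n_sub - 1) / 2) * (da / n_sub)
    angles = (seg_centers[:, None] + offs[None, :]).ravel()  # (n_seg*n_sub,)
    cx, cy = center
    xs = cx + np.outer(np.cos(angles), r_grid)  # px
    ys = cy + np.outer(np.sin(angles), r_grid)
    vals = ndimage.map_coordinates(frame.astype(float), [ys.ravel(), xs.ravel()],
                                   order=1, mode="nearest")
    return vals.reshape(seg_centers.size, n_sub, r_grid.size)


def find_center(frame: np.ndarray, threshold_policy="otsu",
                config: ExtractionConfig | None = None) -> tuple:
    """Intensity centroid of the thresholded membrane ring, in pixels (x, y).

    One refinement pass recomputes the centre from the centroid of the
    extracted contour, which removes the bias a non-uniform ring would
    leave in the raw pixel centroid.
    """
    frame = np.asarray(frame, dtype=float)
    if threshold_policy == "otsu":
        from skimage.filters import threshold_otsu

        if np.ptp(frame) == 0:
            raise EmptyFrameError("uniform frame: no ring to centre on")
        thr = threshold_otsu(frame)
    else:
        thr = float(threshold_policy)
    mask = frame > thr
    if not np.any(mask):
        raise EmptyFrameError("no pixels above threshold")
    w = np.where(mask, frame - thr, 0.0)
    cy, cx = ndimage.center_of_mass(w)
    config = config or ExtractionConfig()
    try:
        phi, radii_um, _ = extract_contour(frame, (cx, cy), config)
        radii_px = radii_um / config.pixel_size
        cx = cx + np.mean(radii_px * np.cos(phi))
        cy = cy + np.mean(radii_px * np.sin(phi))
    except FrameRejectedError:
        pass  # keep the raw centroid
    return (float(cx), float(cy))


def extract_contour(frame: np.ndarray, center: tuple,
                    config: ExtractionConfig, m_phi: int = M_PHI):
    """R(phi) in micrometres on the uniform phi grid.

    Returns ``(phi, radii_um, n_missing)``.  Segments with a flat radial
    profile are marked missing and filled by periodic interpolation;
    frames with more than ``max_missing_fraction`` missing segments
    raise :class:`FrameRejectedError`.
    """
    frame = np.asarray(frame, dtype=float)
    ny, nx = frame.shape
    cx, cy = center
    r_max = min(cx, cy, nx - 1 - cx, ny - 1 - cy)
    if r_max <= 2:
        raise FrameRejectedError("centre too close to the frame edge")
    r_grid = np.arange(2.0, r_max, 0.5)  # px, half-pixel steps
    seg = _segment_angles(config)
    prof = _polar_profiles(frame, center, config, r_grid, seg)  # (n_seg, n_sub, n_r)
    mean_prof = prof.mean(axis=1)
    ptp = mean_prof.max(axis=1) - mean_prof.min(axis=1)
    missing = ptp <= 1e-9 * np.maximum(np.abs(mean_prof).max(axis=1), 1.0)
    n_missing = int(missing.sum())
    if n_missing > config.max_missing_fraction * seg.size:
        raise FrameRejectedError(
            f"{n_missing}/{seg.size} segments without a membrane peak")
    # peak radius per individual sub-ray, then averaged across the segment:
    # peak-finding is done before any angular averaging so that contour
    # slope cannot rectify into spurious high-q harmonics
    n_seg, n_sub, n_r = prof.shape
    rays = prof.reshape(n_seg * n_sub, n_r)
    idx = np.argmax(rays, axis=1)
    r_ray = r_grid[idx].copy()
    # 3-point parabolic subpixel refinement on log intensity (exact for a
    # Gaussian ring profile) after subtracting the local background
    inner = (idx > 0) & (idx < n_r - 1)
    rows = np.flatnonzero(inner)
    i = idx[rows]
    base = rays.min(axis=1)[rows]
    y0, y1, y2 = rays[rows, i - 1] - base, rays[rows, i] - base, \
        rays[rows, i + 1] - base
    pos = (y0 > 0) & (y1 > 0) & (y2 > 0)
    z0 = np.where(pos, np.log(np.where(pos, y0, 1.0)), y0)
    z1 = np.where(pos, np.log(np.where(pos, y1, 1.0)), y1)
    z2 = np.where(pos, np.log(np.where(pos, y2, 1.0)), y2)
    denom = z0 - 2 * z1 + z2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (z0 - z2) / denom, 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    r_ray[rows] += shift * 0.5  # r_grid step is 0.5 px
    # the radius attributed to the segment centre comes from the central
    # sub-rays only (arc ~ dphi/2): the full segment width serves the peak
    # search and the missing-sample test, while a narrow averaging arc
    # keeps high-q modes unattenuated
    mid = n_sub // 2
    sel = slice(max(mid - 1, 0), min(mid + 2, n_sub))
    r_seg = r_ray.reshape(n_seg, n_sub)[:, sel].mean(axis=1)
    if n_missing:
        good = ~missing
        r_seg = np.interp(seg, seg[good], r_seg[good], period=2 * np.pi)
    phi = phi_grid(m_phi)
    # trigonometric resampling: exact for contours band-limited below the
    # segment Nyquist mode (~21 for dphi=0.15), whereas linear interpolation
    # would attenuate high-q modes by its sinc^2 transfer
    from scipy.signal import resample

    radii = resample(r_seg, m_phi) * config.pixel_size
    return phi, radii, n_missing


def extract_density(frame_mt: np.ndarray, contour_radii_um: np.ndarray,
                    center: tuple, config: ExtractionConfig,
                    phi: np.ndarray | None = None) -> np.ndarray:
    """Background-subtracted mean MT intensity in the near-membrane box.

    The box per angular segment spans [R(phi) - dR, R(phi)] radially and
    the segment amplitude ``da`` angularly; the background is the median
    intensity outside R + ``background_offset_um``.  Boxes reaching
    outside the frame are clipped (a warning is raised).
    """
    frame_mt = np.asarray(frame_mt, dtype=float)
    phi = phi_grid(M_PHI) if phi is None else phi
    px = config.pixel_size
    seg = _segment_angles(config)
    R_seg = np.interp(seg, phi, contour_radii_um, period=2 * np.pi) / px  # px
    ny, nx = frame_mt.shape
    cx, cy = center
    r_lim = min(cx, cy, nx - 1 - cx, ny - 1 - cy)
    dR_px = config.density_box_dR / px
    n_r = max(int(np.ceil(dR_px / 0.5)), 3)
    da = config.segment_amplitude_da
    n_sub = 5
    offs = (np.arange(n_sub) - (n_sub - 1) / 2) * (da / n_sub)
    rho = np.empty(seg.size)
    clipped = False
    for j, (p0, Rj) in enumerate(zip(seg, R_seg)):
        r0, r1 = max(Rj - dR_px, 0.5), Rj
        if r1 > r_lim:
            r1 = r_lim
            clipped = True
        rr = np.linspace(r0, r1, n_r)
        ang = p0 + offs
        xs = cx + np.outer(np.cos(ang), rr)
        ys = cy + np.outer(np.sin(ang), rr)
        vals = ndimage.map_coordinates(frame_mt, [ys.ravel(), xs.ravel()],
                                       order=1, mode="nearest")
        rho[j] = vals.mean()
    if clipped:
        warnings.warn("density box clipped at the frame boundary")
    # background ring outside the contour
    bg_r0 = R_seg + config.background_offset_um / px
    bg_vals = []
    for j, p0 in enumerate(seg):
        rr = np.linspace(bg_r0[j], min(bg_r0[j] + dR_px, r_lim), 4)
        if rr[-1] <= rr[0]:
            continue
        xs = cx + np.cos(p0) * rr
        ys = cy + np.sin(p0) * rr
        bg_vals.append(ndimage.map_coordinates(frame_mt, [ys, xs], order=1,
                                               mode="nearest"))
    background = float(np.median(np.concatenate(bg_vals))) if bg_vals else 0.0
    rho_out = np.interp(phi, seg, rho - background, period=2 * np.pi)
    return rho_out


def radial_density_profile(stack_mt: np.ndarray, contours: ContourSeries,
                           centers, config: ExtractionConfig,
                           n_bins: int = 60, r_rel_max: float = 1.3) -> np.ndarray:
    """Azimuthally and temporally averaged intensity versus r/R0.

    Returns an (n_bins, 2) array of (r/R0, mean intensity).  Needs at
    least 10 frames.
    """
    stack_mt = np.asarray(stack_mt, dtype=float)
    if stack_mt.shape[0] < 10:
        raise ValueError("need >= 10 frames for a radial profile")
    R0_px = contours.R0 / config.pixel_size
    r_rel = (np.arange(n_bins) + 0.5) * (r_rel_max / n_bins)
    angles = np.arange(0, 2 * np.pi, 2 * np.pi / 90)
    prof = np.zeros(n_bins)
    for k in range(stack_mt.shape[0]):
        cx, cy = centers[k] if np.ndim(centers) == 2 else centers
        rr = r_rel * R0_px
        xs = cx + np.outer(np.cos(angles), rr)
        ys = cy + np.outer(np.sin(angles), rr)
        vals = ndimage.map_coordinates(stack_mt[k], [ys.ravel(), xs.ravel()],
                                       order=1, mode="nearest")
        prof += vals.reshape(angles.size, n_bins).mean(axis=0)
    prof /= stack_mt.shape[0]
    return np.column_stack([r_rel, prof])


# ---------------------------------------------------------------------------
# Flow
# ---------------------------------------------------------------------------

def compute_flow(density: DensityField, contours: ContourSeries,
                 window: float = 1.0, sector_halfwidth: float = 0.6,
                 n_sectors: int = 36, min_peak_corr: float = 0.2) -> FlowField:
    """Tangential and radial flow near the membrane.

    The tangential speed is measured per angular sector by circular
    cross-correlation of the local density profile between frames spaced
    by the averaging ``window`` (peak lag x R0 / window, subpixel
    parabolic refinement, CCW positive).  The radial speed is the
    membrane displacement over the same window.  Sectors without a
    correlation peak are NaN (flow undefined there).
    """
    if window < contours.dt:
        raise ValueError("averaging window must be >= frame interval")
    nw = max(int(round(window / contours.dt)), 1)
    n = density.n_frames
    if n < 2 * nw:
        raise ValueError("need at least 2 windows of frames")
    phi = density.phi
    m = phi.size
    dphi = 2 * np.pi / m
    R0 = contours.R0
    sec_centers = np.arange(n_sectors) * (2 * np.pi / n_sectors)
    half = int(round(sector_halfwidth / dphi))
    max_shift = half  # search lags within the sector halfwidth
    starts = np.arange(0, n - nw, nw)
    vT = np.full((starts.size, n_sectors), np.nan)
    vR = np.full((starts.size, n_sectors), np.nan)
    for wi, s in enumerate(starts):
        r1 = density.rho[s:s + nw].mean(axis=0)
        r2 = density.rho[s + nw:min(s + 2 * nw, n)].mean(axis=0)
        R_a = contours.radii[s:s + nw].mean(axis=0)
        R_b = contours.radii[s + nw:min(s + 2 * nw, n)].mean(axis=0)
        for j, c in enumerate(sec_centers):
            jc = int(round(c / dphi))
            idx = (jc + np.arange(-half, half + 1)) % m
            s1 = r1[idx] - r1[idx].mean()
            n1 = float(np.sqrt(s1 @ s1))
            if n1 < 1e-12:
                continue
            lags = np.arange(-max_shift, max_shift + 1)
            score = np.full(lags.size, -np.inf)
            for li, l in enumerate(lags):
                idx2 = (idx + l) % m
                s2 = r2[idx2] - r2[idx2].mean()
                n2 = float(np.sqrt(s2 @ s2))
                if n2 < 1e-12:
                    continue
                score[li] = float(s1 @ s2) / (n1 * n2)  # cosine similarity
            pk = int(np.argmax(score))
            if not np.isfinite(score[pk]) or score[pk] < min_peak_corr \
                    or pk in (0, lags.size - 1):
                continue  # no interior correlation peak: flow undefined
            lag = float(lags[pk])
            y0, y1, y2 = score[pk - 1], score[pk], score[pk + 1]
            den = y0 - 2 * y1 + y2
            if np.isfinite(y0) and np.isfinite(y2) and abs(den) > 1e-12:
                lag += float(np.clip(0.5 * (y0 - y2) / den, -1, 1))
            # r2 displaced CCW by lag*dphi relative to r1
            vT[wi, j] = lag * dphi * R0 / window
            sec_R = (jc + np.arange(-half, half + 1)) % m
            vR[wi, j] = float(np.mean(R_b[sec_R] - R_a[sec_R])) / window
    t = (starts + nw / 2) * contours.dt
    speed = np.sqrt(vT**2 + vR**2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        frac = float(np.nanmean(np.abs(vT)) / np.nanmean(speed)) \
            if np.any(np.isfinite(speed)) else np.nan
    return FlowField(phi=sec_centers, t=t, v_tangential=vT, v_radial=vR,
                     averaging_window=window, tangential_fraction=frac)


def density_deformation_correlation(contours: ContourSeries,
                                    density: DensityField):
    """Pooled Pearson r between dR/R0 and rho, plus the mean per-frame
    circular cross-correlation curve.

    Returns ``(r, lags_rad, mean_xcorr)``; r is NaN (undefined) when
    either series is constant.
    """
    defo = (contours.radii - contours.R0) / contours.R0
    rho = density.rho
    if defo.shape != rho.shape:
        raise ValueError("contour and density must share grids")
    if np.ptp(defo) == 0 or np.ptp(rho) == 0:
        return np.nan, None, None
    r = float(np.corrcoef(defo.ravel(), rho.ravel())[0, 1])
    m = defo.shape[1]
    d = defo - defo.mean(axis=1, keepdims=True)
    p = rho - rho.mean(axis=1, keepdims=True)
    D = np.fft.rfft(d, axis=1)
    P = np.fft.rfft(p, axis=1)
    xc = np.fft.irfft(D * np.conj(P), n=m, axis=1)
    denom = (np.linalg.norm(d, axis=1) * np.linalg.norm(p, axis=1))
    good = denom > 0
    xc = (xc[good] / denom[good, None]).mean(axis=0)
    lags = np.fft.fftfreq(m, d=1.0 / m) * (2 * np.pi / m)
    order = np.argsort(np.angle(np.exp(1j * lags)))
    return r, np.angle(np.exp(1j * lags))[order], xc[order]


# ---------------------------------------------------------------------------
# Stack driver
# ---------------------------------------------------------------------------

def extract_stack(membrane_stack: np.ndarray, config: ExtractionConfig,
                  dt: float, mt_stack: np.ndarray | None = None,
                  center: tuple | None = None):
    """Extract a ContourSeries (and DensityField) from image stacks.

    ``center_mode='per-frame'`` recomputes the centre for every frame;
    'fixed' uses the first frame's centre (or an explicit ``center``).
    Rejected frames are dropped; their count is reported.
    Returns ``(contours, density_or_None, n_rejected)``.
    """
    membrane_stack = np.asarray(membrane_stack)
    n = membrane_stack.shape[0]
    phi = phi_grid(M_PHI)
    radii, rhos, centers = [], [], []
    n_rejected = 0
    fixed_center = center
    if config.center_mode == "fixed" and fixed_center is None:
        fixed_center = find_center(membrane_stack[0], config=config)
    for k in range(n):
        try:
            c = fixed_center if config.center_mode == "fixed" else \
                find_center(membrane_stack[k], config=config)
            _, rk, _ = extract_contour(membrane_stack[k], c, config)
        except (EmptyFrameError, FrameRejectedError):
            n_rejected += 1
            continue
        radii.append(rk)
        centers.append((c[0] * config.pixel_size, c[1] * config.pixel_size))
        if mt_stack is not None:
            rhos.append(extract_density(mt_stack[k], rk, c, config, phi))
    if not radii:
        raise FrameRejectedError("all frames rejected")
    contours = ContourSeries(phi=phi, radii=np.asarray(radii), dt=dt,
                             center=np.asarray(centers))
    density = DensityField(phi=phi, rho=np.asarray(rhos), dt=dt) \
        if mt_stack is not None else None
    return contours, density, n_rejected
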