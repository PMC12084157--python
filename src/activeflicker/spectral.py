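"""Flicker-spectroscopy core.

Fourier decomposition of equatorial contours, fluctuation spectra,
Canham-Helfrich fits, 1/e correlation times, power-law exponents and
kurtosis analysis of radial deformations.

The mode convention is fixed package-wide (see ``containers.CONVENTION``):

    R(phi, t) = R0 * (1 + sum_{q=1}^{q_max} [u_q(t) e^{i q phi} + c.c.])

with u_q = (b_q - i a_q) / (2 R0), where a_q and b_q are the sine and
cosine quadrature amplitudes of R(phi) computed by the trapezoidal rule
on the periodic angular grid.  Under this convention the prescribed
equatorial spectrum of a passive quasi-spherical vesicle is

    <|u_q|^2> = C_CONV * (k_BT / kappa) / (q^3 + sigma_bar * q),

with C_CONV = 1/2 and sigma_bar = sigma R0^2 / (kappa k_BT).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, stats

from .containers import (
    ContourSeries,
    CorrelationTimes,
    DensityField,
    HelfrichFit,
    KurtosisResult,
    ModeTrajectory,
    SpectrumResult,
    CONVENTION,
)
from .params import C_CONV, KB


# ---------------------------------------------------------------------------
# Fourier decomposition
# ---------------------------------------------------------------------------

def _quadrature_coefficients(values: np.ndarray, phi: np.ndarray, q_max: int):
    """Trapezoidal a_q = (1/pi) int f sin(q phi) dphi and b_q (cosine).

    ``values`` may be (M,) or (n_frames, M).  The grid must be uniform and
    periodic on [0, 2pi); the wrap point is added internally so that the
    trapezoidal rule closes the contour.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    phi = np.asarray(phi, dtype=float)
    m = phi.size
    dphi = np.diff(phi)
    if not np.allclose(dphi, dphi[0], rtol=1e-8, atol=1e-12):
        raise ValueError("angular grid must be uniform; resample first")
    phi_c = np.concatenate([phi, [phi[0] + 2.0 * np.pi]])
    vals_c = np.concatenate([values, values[:, :1]], axis=1)
    qs = np.arange(1, q_max + 1)
    sin_b = np.sin(np.outer(qs, phi_c))  # (n_q, M+1)
    cos_b = np.cos(np.outer(qs, phi_c))
    a = np.trapezoid(vals_c[:, None, :] * sin_b[None, :, :], phi_c, axis=2) / np.pi
    b = np.trapezoid(vals_c[:, None, :] * cos_b[None, :, :], phi_c, axis=2) / np.pi
    return a, b


def decompose_contour(contour: ContourSeries | np.ndarray, q_max: int = 15,
                      phi: np.ndarray | None = None, dt: float = 1.0,
                      normalize: bool = True) -> ModeTrajectory:
    """Decompose contour frames into complex Fourier modes u_q(t).

    Accepts a :class:`ContourSeries` or a raw (n_frames, M) array with an
    explicit ``phi`` grid.  Requires at least ``2 q_max + 1`` angular
    samples.  q = 0 information is retained as the per-frame mean radius in
    ``R0`` (series mean) and is not part of the returned modes.

    With ``normalize=False`` the coefficients keep the physical units of
    the input field (used for density modes).
    """
    if isinstance(contour, ContourSeries):
        values = contour.radii
        phi = contour.phi
        dt = contour.dt
        R0 = contour.R0
    else:
        if phi is None:
            raise ValueError("phi grid required for raw arrays")
        values = np.atleast_2d(np.asarray(contour, dtype=float))
        R0 = float(np.mean(values))
    if phi.size < 2 * q_max + 1:
        raise ValueError(
            f"need >= {2 * q_max + 1} angular samples for q_max={q_max}, got {phi.size}")
    a, b = _quadrature_coefficients(values, phi, q_max)
    scale = 2.0 * R0 if normalize else 2.0
    u = (b - 1j * a) / scale
    return ModeTrajectory(q_values=np.arange(1, q_max + 1), coefficients=u,
                          dt=dt, R0=R0 if normalize else 1.0,
                          convention=CONVENTION)


def reconstruct_contour(modes: ModeTrajectory, phi: np.ndarray) -> np.ndarray:
    """Real contour R(phi, t) from the conjugate-symmetric mode sum."""
    phi = np.asarray(phi, dtype=float)
    phases = np.exp(1j * np.outer(modes.q_values, phi))  # (n_q, M)
    fluct = 2.0 * np.real(modes.coefficients @ phases)  # (n_frames, M)
    return modes.R0 * (1.0 + fluct)


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def fluctuation_spectrum(modes: ModeTrajectory, n_blocks: int = 10,
                         n_boot: int = 200, seed: int = 0) -> SpectrumResult:
    """Per-mode time variance of u_q with SEM from a block bootstrap.

    The temporal mean of each mode is removed before squaring.  Blocks are
    contiguous segments of the time series; their length should exceed the
    mode correlation time for the SEM to be trustworthy, so ``n_blocks``
    defaults to a coarse partition (20 blocks).  With fewer than 3 usable
    blocks the SEM is undefined (NaN).
    """
    u = modes.coefficients
    n = u.shape[0]
    if n < 100:
        raise ValueError("need at least 100 frames for a spectrum")
    du = u - u.mean(axis=0, keepdims=True)
    p_t = np.abs(du) ** 2  # (n, n_q)
    power = p_t.mean(axis=0)
    n_blocks = min(n_blocks, n)
    if n_blocks >= 3:
        blocks = np.array_split(p_t, n_blocks, axis=0)
        bm = np.stack([blk.mean(axis=0) for blk in blocks])  # (n_blocks, n_q)
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n_blocks, size=(n_boot, n_blocks))
        boots = bm[idx].mean(axis=1)  # (n_boot, n_q)
        sem = boots.std(axis=0, ddof=1)
    else:
        sem = np.full(power.shape, np.nan)
    return SpectrumResult(q_values=modes.q_values.copy(), power=power,
                          sem=sem, n_frames=n)


def fit_powerlaw(x: np.ndarray, y: np.ndarray,
                 fit_range: tuple | None = None):
    """Least-squares slope of log y vs log x; returns (exponent, stderr).

    ``fit_range`` restricts to x in [lo, hi] inclusive.  All points must be
    positive; fewer than 2 points is an error, with exactly 2 the standard
    error is undefined (NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    if fit_range is not None:
        mask &= (x >= fit_range[0]) & (x <= fit_range[1])
    x, y = x[mask], y[mask]
    if x.size < 2:
        raise ValueError("need at least 2 points to fit a power law")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires positive values")
    lx, ly = np.log(x), np.log(y)
    A = np.vstack([lx, np.ones_like(lx)]).T
    coef, res, _, _ = np.linalg.lstsq(A, ly, rcond=None)
    slope = coef[0]
    if x.size > 2:
        dof = x.size - 2
        s2 = float(res[0]) / dof if res.size else 0.0
        cov = s2 * np.linalg.inv(A.T @ A)
        err = float(np.sqrt(cov[0, 0]))
    else:
        err = np.nan
    return float(slope), err


def fit_helfrich(spectrum: SpectrumResult, R0: float, temperature: float = 300.0,
                 fit_range: tuple | None = None) -> HelfrichFit:
    """Fit the equatorial quasi-spherical spectrum for (kappa, sigma_bar).

    Model: log<|u_q|^2> = log[C_CONV / kappa] - log(q^3 + sigma_bar q),
    kappa in k_BT units.  Weighted least squares in log space with
    inverse-variance weights from the per-mode SEM, initialised by a
    log-linear fit at sigma_bar = 0 and refined with bounded
    Levenberg-style optimisation.  Tension is recovered as
    sigma = sigma_bar * kappa * k_BT / R0^2.

    ``fit_range`` defaults to q = 3..q_max: q = 1 is the translation mode
    and q = 2 is commonly contaminated by global constraints.
    """
    q = np.asarray(spectrum.q_values, dtype=float)
    p = np.asarray(spectrum.power, dtype=float)
    sem = np.asarray(spectrum.sem, dtype=float)
    if fit_range is None:
        fit_range = (3, int(q.max()))
    mask = (q >= fit_range[0]) & (q <= fit_range[1]) & np.isfinite(p)
    if np.any(p[mask] <= 0):
        raise ValueError("non-positive spectrum entries in fit range")
    q, p, sem = q[mask], p[mask], sem[mask]
    if q.size < 3:
        raise ValueError("need >= 3 modes in fit range")
    logp = np.log(p)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = p / sem  # d log p = d p / p
    w = np.where(np.isfinite(w) & (w > 0), w, 1.0)
    w /= w.max()

    # init: sigma_bar = 0 -> log p = log(C/kappa) - 3 log q
    kappa0 = C_CONV * np.exp(-np.average(logp + 3.0 * np.log(q), weights=w**2))

    def resid(theta):
        log_kappa, log_sbar = theta
        sbar = np.exp(np.clip(log_sbar, -60.0, 60.0))
        model = np.log(C_CONV) - log_kappa - np.log(q**3 + sbar * q)
        return w * (logp - model)

    best = None
    for sbar0 in (1e-6, 1.0, 100.0):
        sol = optimize.least_squares(
            resid, x0=[np.log(kappa0), np.log(sbar0)], method="lm", max_nfev=2000)
        if best is None or sol.cost < best.cost:
            best = sol
    kappa_hat = float(np.exp(best.x[0]))
    sigma_bar_hat = float(np.exp(best.x[1]))
    # covariance in (log kappa, log sbar)
    dof = max(q.size - 2, 1)
    J = best.jac
    cov = np.linalg.pinv(J.T @ J) * 2.0 * best.cost / dof
    kappa_err = kappa_hat * float(np.sqrt(abs(cov[0, 0])))
    sigma_bar_err = sigma_bar_hat * float(np.sqrt(abs(cov[1, 1])))
    below_res = sigma_bar_hat < 1e-4
    R0_m = R0 * 1e-6
    sigma_hat = sigma_bar_hat * kappa_hat * KB * temperature / R0_m**2
    return HelfrichFit(
        kappa_hat=kappa_hat, sigma_bar_hat=sigma_bar_hat, sigma_hat=sigma_hat,
        kappa_err=kappa_err, sigma_bar_err=sigma_bar_err,
        fit_range=tuple(fit_range), residuals=resid(best.x), covariance=cov,
        tension_below_resolution=below_res)


_Y2_CACHE: dict = {}


def equatorial_power_quasispherical(q_values, kappa: float, sigma_bar: float,
                                    l_max: int = 80) -> np.ndarray:
    """Exact equatorial mode spectrum of a 3D quasi-spherical vesicle.

    The printed ring formula C_CONV (kBT/kappa)/(q^3 + sigma_bar q) is a
    2D stand-in; the equatorial cross-section of a fluctuating sphere
    sums every spherical harmonic l >= q evaluated on the equator:

        <|u_q|^2> = sum_{l>=max(q,2)} |Y_lq(pi/2)|^2
                     / [kappa (l-1)(l+2) (l(l+1) + sigma_bar)]

    (kappa in kBT).  The sum preserves the ~q^-3 bending and ~q^-1
    tension scalings but carries a ~10x smaller prefactor; it is the
    correct measurement model for equatorial sections of 3D simulations.
    """
    from scipy.special import sph_harm_y

    q_values = np.atleast_1d(np.asarray(q_values, dtype=int))
    out = np.zeros(q_values.shape)
    for i, q in enumerate(q_values):
        s = 0.0
        for l in range(max(int(q), 2), l_max):
            key = (l, int(q))
            if key not in _Y2_CACHE:
                _Y2_CACHE[key] = float(
                    np.abs(sph_harm_y(l, int(q), np.pi / 2, 0.0)) ** 2)
            s += _Y2_CACHE[key] / ((l - 1) * (l + 2) * (l * (l + 1) + sigma_bar))
        out[i] = s / kappa
    return out


def fit_helfrich_equatorial(spectrum: SpectrumResult, R0: float,
                            temperature: float = 300.0,
                            fit_range: tuple | None = None,
                            l_max: int = 80) -> HelfrichFit:
    """Fit (kappa, sigma_bar) with the exact quasi-spherical equatorial
    model (see :func:`equatorial_power_quasispherical`).

    Intended for equatorial sections of genuinely three-dimensional
    shapes (e.g. the triangulated-vesicle simulator), where the 2D ring
    formula of :func:`fit_helfrich` would overestimate kappa by roughly
    the prefactor ratio (~10x)."""
    q = np.asarray(spectrum.q_values, dtype=int)
    p = np.asarray(spectrum.power, dtype=float)
    if fit_range is None:
        fit_range = (3, int(q.max()))
    mask = (q >= fit_range[0]) & (q <= fit_range[1]) & np.isfinite(p)
    if np.any(p[mask] <= 0):
        raise ValueError("non-positive spectrum entries in fit range")
    qf, pf = q[mask], p[mask]

    def resid(theta):
        kappa, sbar = np.exp(theta)
        return np.log(pf) - np.log(
            equatorial_power_quasispherical(qf, kappa, sbar, l_max))

    best = None
    for s0 in (0.1, 10.0, 300.0):
        sol = optimize.least_squares(resid, x0=[np.log(20.0), np.log(s0)],
                                     method="lm", max_nfev=400)
        if best is None or sol.cost < best.cost:
            best = sol
    kappa_hat, sigma_bar_hat = np.exp(best.x)
    dof = max(qf.size - 2, 1)
    cov = np.linalg.pinv(best.jac.T @ best.jac) * 2.0 * best.cost / dof
    R0_m = R0 * 1e-6
    return HelfrichFit(
        kappa_hat=float(kappa_hat), sigma_bar_hat=float(sigma_bar_hat),
        sigma_hat=float(sigma_bar_hat * kappa_hat * KB * temperature / R0_m**2),
        kappa_err=float(kappa_hat * np.sqrt(abs(cov[0, 0]))),
        sigma_bar_err=float(sigma_bar_hat * np.sqrt(abs(cov[1, 1]))),
        fit_range=tuple(fit_range), residuals=resid(best.x), covariance=cov,
        tension_below_resolution=bool(sigma_bar_hat < 1e-3))


# ---------------------------------------------------------------------------
# Correlation times
# ---------------------------------------------------------------------------

def _autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased (1/N) autocorrelation Re<x(t+tau) x*(t)> via FFT, de-meaned."""
    x = x - x.mean()
    n = x.size
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    X = np.fft.fft(x, nfft)
    acf = np.fft.ifft(X * np.conj(X))[:max_lag + 1]
    return np.real(acf) / n


def correlation_times(modes: ModeTrajectory, max_lag_frac: float = 0.5,
                      keep_curves: bool = False) -> CorrelationTimes:
    """1/e-crossing correlation time of each complex mode.

    The normalized autocorrelation Re<u_q(t+tau) u_q*(t)> / <|u_q|^2> is
    computed with the biased (divide-by-N) estimator; the first
    down-crossing of 1/e is located by linear interpolation between lag
    samples.  Modes that never cross within ``max_lag_frac`` of the
    trajectory are flagged NaN.  A crossing before the first lag sample is
    resolution-limited and reported as tau <= dt (value dt, flagged in the
    curves as crossing at or before the first lag).
    """
    n = modes.n_frames
    max_lag = max(int(n * max_lag_frac), 2)
    taus = np.full(modes.q_values.shape, np.nan)
    curves = np.zeros((modes.q_values.size, max_lag + 1)) if keep_curves else None
    target = 1.0 / np.e
    for k in range(modes.q_values.size):
        acf = _autocorrelation(modes.coefficients[:, k], max_lag)
        if acf[0] <= 0:
            continue
        c = acf / acf[0]
        if keep_curves:
            curves[k] = c
        below = np.flatnonzero(c < target)
        if below.size == 0:
            continue
        i = below[0]
        if i == 0:
            continue  # cannot happen: c[0] = 1
        # linear interpolation between (i-1, i)
        frac = (c[i - 1] - target) / (c[i - 1] - c[i])
        taus[k] = (i - 1 + frac) * modes.dt
    lags = np.arange(max_lag + 1) * modes.dt if keep_curves else None
    return CorrelationTimes(q_values=modes.q_values.copy(), tau=taus,
                            correlation_curves=curves, lags=lags)


# ---------------------------------------------------------------------------
# Kurtosis
# ---------------------------------------------------------------------------

def kurtosis_analysis(contour: ContourSeries, tau_avg_list,
                      min_window_samples: int = 20) -> KurtosisResult:
    """Excess kurtosis of pooled radial deformations per averaging window.

    For each tau_avg the deformation series (R - R0)/R0 (R0 the global
    time-phi mean) is split into disjoint windows of tau_avg seconds; all
    (phi, t) samples within a window are pooled and the bias-corrected
    excess kurtosis computed.  Mean/sd/min/max across windows are
    returned, together with the mean pooled variance per window.
    Windows shorter than ``min_window_samples`` frames are skipped with a
    warning.
    """
    tau_avg_list = np.asarray(tau_avg_list, dtype=float)
    defo = contour.deformation / contour.R0  # (n, M)
    n = defo.shape[0]
    means, sds, mins, maxs, variances = [], [], [], [], []
    kept = []
    for tau_avg in tau_avg_list:
        w = int(round(tau_avg / contour.dt))
        if w < min_window_samples:
            warnings.warn(
                f"tau_avg={tau_avg} s gives {w} frames < {min_window_samples}; skipped")
            continue
        n_win = n // w
        if n_win < 1:
            warnings.warn(f"series shorter than tau_avg={tau_avg} s; skipped")
            continue
        ks, vs = [], []
        for i in range(n_win):
            pooled = defo[i * w:(i + 1) * w].ravel()
            ks.append(stats.kurtosis(pooled, fisher=True, bias=False))
            vs.append(np.var(pooled))
        ks = np.asarray(ks)
        kept.append(tau_avg)
        means.append(ks.mean())
        sds.append(ks.std(ddof=1) if ks.size > 1 else np.nan)
        mins.append(ks.min())
        maxs.append(ks.max())
        variances.append(float(np.mean(vs)))
    return KurtosisResult(
        tau_avg_values=np.asarray(kept), mean=np.asarray(means),
        sd=np.asarray(sds), min=np.asarray(mins), max=np.asarray(maxs),
        variance=np.asarray(variances))


# ---------------------------------------------------------------------------
# Density modes
# ---------------------------------------------------------------------------

def density_spectrum_and_times(density: DensityField, q_max: int = 15,
                               normalize_at_q2: bool = True):
    """Spectrum and 1/e correlation times of the angular density modes.

    The density rho(phi, t) is mean-subtracted and run through the same
    decomposition/spectrum/correlation pipeline as the contour.  For
    cross-condition comparison the reported spectrum is normalized to 1 at
    q = 2 (the raw variance stays available through the returned mode
    trajectory).
    """
    rho = density.rho - density.rho.mean()
    modes = decompose_contour(rho, q_max=q_max, phi=density.phi,
                              dt=density.dt, normalize=False)
    spec = fluctuation_spectrum(modes)
    if normalize_at_q2:
        i2 = np.flatnonzero(spec.q_values == 2)
        if i2.size and spec.power[i2[0]] > 0:
            norm = spec.power[i2[0]]
            spec = SpectrumResult(q_values=spec.q_values,
                                  power=spec.power / norm,
                                  sem=spec.sem / norm,
                                  n_frames=spec.n_frames)
    times = correlation_times(modes)
    return spec, times, modes
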