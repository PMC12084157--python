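"""Synthetic vesicle dynamics with known ground truth.

Two generators:

* :func:`simulate_passive_modes` -- each equatorial Fourier mode is an
  independent stationary Ornstein-Uhlenbeck process with the
  quasi-spherical variance <|u_q|^2> = C_CONV (k_BT/kappa)/(q^3 +
  sigma_bar q) and relaxation time tau_q = 4 eta R0^3 / (kappa_SI (q^3 +
  sigma_bar q)).

* :func:`simulate_active_record` -- a birth-death population of angular
  density bumps advected tangentially at angular speed omega = v/R0;
  each bump carries a co-moving membrane deformation whose mode content
  follows a prescribed power law, so deformation maxima co-locate with
  density maxima by construction.

Everything is a pure function of (params, seed).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.signal import lfilter

from .containers import (
    ContourSeries,
    DensityField,
    ModeTrajectory,
    SyntheticRecord,
    CONVENTION,
    M_PHI,
    phi_grid,
)
from .params import ActiveNoiseParams, MembraneParams


# ---------------------------------------------------------------------------
# Passive thermal modes
# ---------------------------------------------------------------------------

def simulate_passive_modes(params: MembraneParams, n_modes: int = 15,
                           dt: float = 0.2, n_steps: int = 5000,
                           seed: int = 0, q_min: int = 1,
                           enforce_dt: bool = True) -> ModeTrajectory:
    """Stationary OU dynamics of the equatorial modes q = q_min..n_modes.

    Real and imaginary parts of each u_q evolve as independent OU
    processes with variance <|u_q|^2>/2 each; the first sample is drawn
    from the stationary law, so no burn-in is needed.  ``dt`` must
    resolve the fastest relaxation time tau_{q_max}; the exact AR(1)
    update remains statistically correct at any dt (modes with tau << dt
    sample as white noise), so ``enforce_dt=False`` disables the guard
    for background-noise use where only the stationary law matters.
    """
    if n_modes < 2:
        raise ValueError("n_modes must be >= 2")
    qs = np.arange(q_min, n_modes + 1)
    var = params.mode_variance(qs)
    tau = params.relaxation_time(qs)
    if enforce_dt and dt >= tau[-1]:
        raise ValueError(
            f"dt={dt} s does not resolve tau_qmax={tau[-1]:.3g} s; "
            "reduce dt below the shortest relaxation time")
    rng = np.random.default_rng(seed)
    rho = np.exp(-dt / tau)  # (n_q,)
    u = np.empty((n_steps, qs.size), dtype=complex)
    for k in range(qs.size):
        s = np.sqrt(var[k] / 2.0)  # stationary sd of each quadrature
        innov_sd = s * np.sqrt(1.0 - rho[k] ** 2)
        noise = rng.standard_normal((n_steps, 2)) * innov_sd
        noise[0] = rng.standard_normal(2) * s  # stationary start
        re = lfilter([1.0], [1.0, -rho[k]], noise[:, 0])
        im = lfilter([1.0], [1.0, -rho[k]], noise[:, 1])
        u[:, k] = re + 1j * im
    return ModeTrajectory(q_values=qs, coefficients=u, dt=dt, R0=params.R0,
                          convention=CONVENTION)


def passive_contour(params: MembraneParams, n_modes: int = 15, dt: float = 0.2,
                    n_steps: int = 5000, seed: int = 0,
                    m_phi: int = M_PHI,
                    enforce_dt: bool = True) -> SyntheticRecord:
    """Passive record: contour series rebuilt from simulated thermal modes.

    The q = 1 translation mode is excluded from the contour (a pure
    shift of the centre carries no shape information).  ``enforce_dt``
    as in :func:`simulate_passive_modes`: disable it when only the
    stationary shape statistics matter (e.g. stiff-membrane limits).
    """
    modes = simulate_passive_modes(params, n_modes=n_modes, dt=dt,
                                   n_steps=n_steps, seed=seed, q_min=2,
                                   enforce_dt=enforce_dt)
    phi = phi_grid(m_phi)
    from .spectral import reconstruct_contour

    radii = reconstruct_contour(modes, phi)
    contour = ContourSeries(phi=phi, radii=radii, dt=dt)
    return SyntheticRecord(contour=contour, density=None, mode_truth=modes,
                           membrane=params, active=None, seed=seed)


# ---------------------------------------------------------------------------
# Active travelling bumps
# ---------------------------------------------------------------------------

def _bump_mode_weights(active: ActiveNoiseParams, q_max: int) -> np.ndarray:
    """Per-mode amplitude c_q of one bump's deformation pattern, q=2..q_max.

    c_q proportional to q**(spectrum_exponent/2), normalized so that the
    peak deformation of a unit-amplitude bump equals ``active.amplitude``:
    Delta(phi) = a(t) * sum_q 2 c_q cos(q (phi - phi_b)), peak = 2 sum c_q.
    """
    qs = np.arange(2, q_max + 1, dtype=float)
    c = qs ** (active.spectrum_exponent / 2.0)
    c *= active.amplitude / (2.0 * c.sum())
    return c


def thermal_background_params(membrane: MembraneParams,
                              active: ActiveNoiseParams,
                              q_max: int = 15,
                              amplitude_fraction: float = 0.1) -> MembraneParams:
    """Stiffened membrane parameters giving a thermal floor at a fixed
    fraction of the active mode amplitude.

    Active vesicles fluctuate roughly an order of magnitude above the
    passive reference at all modes; with the default bump spectrum
    exponent of -3 a tensionless thermal background has the same q
    dependence, so a single rescaled rigidity puts the thermal amplitude
    at ``amplitude_fraction`` of the active one uniformly in q.
    """
    c = _bump_mode_weights(active, q_max)
    if c[0] == 0.0:
        return membrane
    n_mean = active.birth_rate * active.lifetime_Ta
    # <a^2> for the sin^2 envelope averaged over a bump's life is 3/8
    p2_active = max(n_mean, 1e-12) * 0.375 * c[0] ** 2  # power at q=2
    p2_target = (amplitude_fraction ** 2) * p2_active
    from .params import C_CONV

    kappa_bg = C_CONV / (p2_target * 8.0)  # sigma_bar = 0, q=2 -> q^3 = 8
    return replace(membrane, kappa=kappa_bg, sigma=0.0)


def simulate_active_record(membrane: MembraneParams, active: ActiveNoiseParams,
                           dt: float = 0.2, n_steps: int = 3000, seed: int = 0,
                           q_max: int = 15, m_phi: int = M_PHI,
                           thermal_background: MembraneParams | None | bool = True,
                           ) -> SyntheticRecord:
    """Birth-death population of travelling density bumps deforming the
    membrane, plus an optional passive thermal background.

    Each bump is born at rate ``birth_rate`` with an exponential lifetime
    (mean ``lifetime_Ta``), a direction drawn once (CCW with probability
    ``direction_switching``), a sin^2 amplitude envelope over its life,
    and is advected at angular speed omega = speed_v / R0.  The bump
    population is initialised from its stationary law (length-biased
    lifetimes, uniform ages).

    ``thermal_background=True`` uses :func:`thermal_background_params`
    (thermal floor at 10% of the active amplitude); pass explicit
    :class:`MembraneParams` or ``None``/``False`` to override.
    """
    T_total = n_steps * dt
    expected = active.birth_rate * T_total
    has_background = thermal_background not in (None, False)
    if expected < 1.0 and active.birth_rate * active.lifetime_Ta < 0.5 \
            and not has_background:
        raise ValueError(
            "no bumps expected during the run and no thermal background: "
            "increase birth_rate, lifetime or n_steps, or enable the background")
    if active.amplitude == 0 and not has_background:
        raise ValueError("zero bump amplitude and no thermal background")

    rng = np.random.default_rng(seed)
    omega = active.speed_v / membrane.R0

    # --- bump population: stationary init + Poisson births -----------------
    births, lifetimes, phis0, dirs = [], [], [], []
    n0 = rng.poisson(active.birth_rate * active.lifetime_Ta)
    for _ in range(n0):
        # length-biased lifetime = sum of two exponentials; age uniform
        life = rng.exponential(active.lifetime_Ta) + rng.exponential(active.lifetime_Ta)
        age = rng.uniform(0.0, life)
        births.append(-age)
        lifetimes.append(life)
        phis0.append(rng.uniform(0.0, 2.0 * np.pi))
        dirs.append(1.0 if rng.uniform() < active.direction_switching else -1.0)
    n_new = rng.poisson(active.birth_rate * T_total)
    for t_birth in np.sort(rng.uniform(0.0, T_total, n_new)):
        births.append(t_birth)
        lifetimes.append(rng.exponential(active.lifetime_Ta))
        phis0.append(rng.uniform(0.0, 2.0 * np.pi))
        dirs.append(1.0 if rng.uniform() < active.direction_switching else -1.0)
    births = np.asarray(births)
    lifetimes = np.asarray(lifetimes)
    phis0 = np.asarray(phis0)
    dirs = np.asarray(dirs)

    c_q = _bump_mode_weights(active, q_max)
    qs_act = np.arange(2, q_max + 1)
    phi = phi_grid(m_phi)
    t = np.arange(n_steps) * dt

    u_act = np.zeros((n_steps, q_max - 1), dtype=complex)
    rho = np.zeros((n_steps, m_phi))
    for b in range(births.size):
        age = t - births[b]
        alive = (age >= 0.0) & (age < lifetimes[b])
        if not np.any(alive):
            continue
        env = np.sin(np.pi * age[alive] / lifetimes[b]) ** 2  # unit envelope
        phi_b = phis0[b] + dirs[b] * omega * age[alive]
        # deformation modes, co-moving with the bump (c_q carries the amplitude)
        u_act[alive] += env[:, None] * c_q[None, :] \
            * np.exp(-1j * np.outer(phi_b, qs_act))
        # density: wrapped-Gaussian bump, amplitude tied to the envelope
        d = np.angle(np.exp(1j * (phi[None, :] - phi_b[:, None])))
        rho[alive] += env[:, None] * np.exp(-d**2 / (2.0 * active.width_w**2))

    # --- thermal background -------------------------------------------------
    if thermal_background is True:
        bg_params = thermal_background_params(membrane, active, q_max)
    elif has_background:
        bg_params = thermal_background
    else:
        bg_params = None
    qs_all = np.arange(1, q_max + 1)
    u = np.zeros((n_steps, q_max), dtype=complex)
    u[:, 1:] = u_act
    if bg_params is not None:
        bg = simulate_passive_modes(bg_params, n_modes=q_max, dt=dt,
                                    n_steps=n_steps,
                                    seed=int(rng.integers(0, 2**31)), q_min=2,
                                    enforce_dt=False)
        u[:, 1:] += bg.coefficients

    modes = ModeTrajectory(q_values=qs_all, coefficients=u, dt=dt,
                           R0=membrane.R0, convention=CONVENTION)
    from .spectral import reconstruct_contour

    radii = reconstruct_contour(modes, phi)
    contour = ContourSeries(phi=phi, radii=radii, dt=dt)
    density = DensityField(phi=phi, rho=rho, dt=dt)
    return SyntheticRecord(contour=contour, density=density, mode_truth=modes,
                           membrane=membrane, active=active, seed=seed)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def passive_preset(seed: int = 0, n_steps: int = 5000, dt: float = 0.2,
                   kappa: float = 13.4, sigma: float = 0.0,
                   R0: float = 25.0) -> SyntheticRecord:
    """Bending-dominated passive vesicle (egg-PC-like rigidity)."""
    return passive_contour(MembraneParams(kappa=kappa, sigma=sigma, R0=R0),
                           n_steps=n_steps, dt=dt, seed=seed)


def active_preset(seed: int = 0, n_steps: int = 3000, dt: float = 0.2,
                  **overrides) -> SyntheticRecord:
    """Default active vesicle: travelling bumps at v = 1 um/s on R0 = 25 um."""
    membrane = MembraneParams(kappa=13.4, sigma=0.0, R0=25.0)
    active = ActiveNoiseParams(**overrides)
    return simulate_active_record(membrane, active, dt=dt, n_steps=n_steps,
                                  seed=seed)
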