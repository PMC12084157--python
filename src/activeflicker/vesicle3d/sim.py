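"""Driver for the triangulated-vesicle Monte Carlo.

Physical picture: a fluid membrane (dynamically triangulated network
with bond flips) of diameter D = 40 um, bending rigidity kappa = 20 kBT
and tension sigma = 1e-8 N/m, enclosing N_fil = 20 extensile bead-spring
filaments with relaxed length L = D/2 that grow to L_max = 2D over T_str
and shrink back, interacting with the membrane by pure repulsion.  Area
and volume are held by harmonic constraints.  Monte Carlo time is mapped
to seconds by matching the passive relaxation time of mode q = 3
(:func:`calibrate_timescale`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ..containers import ContourSeries, ModeTrajectory, phi_grid
from ..params import KB, MembraneParams
from . import mc
from .filaments import FilamentSet, growth_update, init_filaments
from .mesh import MembraneMesh, build_vesicle, mean_bond_length, total_area, \
    total_volume

#: dihedral (1 - cos) prefactor reproducing continuum rigidity kappa
KT_FACTOR = np.sqrt(3.0)


@dataclass
class SimConfig:
    n_vertices: int = 642
    diameter: float = 40.0  # um
    kappa: float = 20.0  # kBT
    sigma_SI: float = 1.0e-8  # N/m
    temperature: float = 300.0  # K
    reduced_volume: float = 1.0
    area_modulus: float = 100.0  # kBT / um^2 (harmonic area constraint)
    volume_modulus: float = 15.0  # kBT / um^3
    delta: float = 0.15  # um, MC move size (auto-tuned)
    flip_fraction: float = 0.2  # fraction of edges attempted per sweep
    # filaments
    n_fil: int = 20
    n_beads: int = 20
    L_over_D: float = 0.5
    Lmax_over_D: float = 2.0
    T_str_sweeps: float = np.inf  # growth time in sweeps (inf = static)
    k_bond: float = 30.0  # kBT / um^2 (soft: growth drives buckling, not spearing)
    k_angle: float = 50.0  # kBT (floppy bundles buckle against the membrane)
    k_rep: float = 1000.0  # kBT
    rc_factor: float = 1.2  # repulsion range in units of mean bond length

    @property
    def sigma_kBT_um2(self) -> float:
        return self.sigma_SI * 1e-12 / (KB * self.temperature)


def membrane_energy(mesh: MembraneMesh, kappa: float, sigma: float = 0.0,
                    area_modulus: float = 0.0,
                    volume_modulus: float = 0.0) -> dict:
    """Energy terms of a mesh configuration, in kBT.

    Bending uses the edge-dihedral form E_b = kt sum_e (1 - cos theta_e)
    with kt = sqrt(3) kappa; tension is sigma*A (sigma in kBT/um^2);
    area and volume penalties are harmonic about the stored targets.
    Degenerate triangles make the energy infinite (move rejection).
    """
    verts, tris = mesh.verts, mesh.tris
    from .mesh import triangle_areas

    areas = triangle_areas(verts, tris)
    if np.any(areas < 1e-12):
        return {"bending": np.inf, "tension": np.inf, "area_penalty": np.inf,
                "volume_penalty": np.inf, "total": np.inf}
    kt = KT_FACTOR * kappa
    eb = 0.0
    for e in range(mesh.n_edges):
        c = mc._edge_bend_cos(verts, tris, mesh.e_t, e)
        if c < -1.5:
            return {"bending": np.inf, "total": np.inf}
        eb += kt * (1.0 - c)
    A = float(areas.sum())
    V = total_volume(verts, tris)
    ea = area_modulus * (A - mesh.area_target) ** 2 / mesh.area_target \
        if mesh.area_target else 0.0
    ev = volume_modulus * (V - mesh.volume_target) ** 2 / mesh.volume_target \
        if mesh.volume_target else 0.0
    et = sigma * A
    return {"bending": eb, "tension": et, "area_penalty": ea,
            "volume_penalty": ev, "total": eb + et + ea + ev,
            "area": A, "volume": V}


@dataclass
class SimMeasurement:
    contours: ContourSeries
    force_modes: ModeTrajectory | None
    mean_force: float  # kBT/um per equatorial vertex
    sigma_act_SI: float  # N/m from the equatorial spectrum fit
    kappa_hat: float  # kBT, from the quasi-spherical equatorial fit
    sigma_bar_hat: float
    area_trace: np.ndarray
    volume_trace: np.ndarray
    flagged_frames: int


class VesicleSim:
    """Metropolis dynamics of the vesicle + filament system.

    All randomness is derived from ``seed``; a run is reproducible from
    (config, seed).  ``passive=True`` removes the filaments.
    """

    def __init__(self, config: SimConfig, seed: int = 0,
                 passive: bool = False):
        self.config = config
        self.seed = int(seed)
        self.rng = np.random.default_rng(seed)
        self.mesh = build_vesicle(config.n_vertices, config.diameter,
                                  reduced_volume=config.reduced_volume)
        self.A = total_area(self.mesh.verts, self.mesh.tris)
        self.V = total_volume(self.mesh.verts, self.mesh.tris)
        self.t_sweeps = 0
        self.delta = config.delta
        l0 = mean_bond_length(self.mesh)
        self.rc = config.rc_factor * l0
        self.passive = passive
        if passive or config.n_fil == 0:
            self.filaments = None
        else:
            self.filaments = init_filaments(
                config.n_fil, config.n_beads,
                config.L_over_D * config.diameter,
                config.Lmax_over_D * config.diameter,
                config.T_str_sweeps, config.diameter / 2.0,
                seed=int(self.rng.integers(2**31)),
                bending_stiffness=config.k_angle)
        self._acc_hist = []

    # -- dynamics -----------------------------------------------------------

    def step_dynamics(self, n_sweeps: int, tune: bool = True) -> None:
        cfg = self.config
        m = self.mesh
        n_flip = int(cfg.flip_fraction * m.n_edges)
        if self.filaments is not None:
            fil_flat = self.filaments.positions.reshape(-1, 3)
            n_beads = self.filaments.n_beads
        else:
            fil_flat = np.zeros((0, 3))
            n_beads = 1
        for _ in range(n_sweeps):
            if self.filaments is not None:
                r0 = growth_update(self.filaments, self.t_sweeps - 1,
                                   self.t_sweeps, cfg.diameter / 2.0, self.rng)
                fil_flat = self.filaments.positions.reshape(-1, 3)
                r0_arr = np.asarray(r0, dtype=float)
            else:
                r0_arr = np.ones(1)
            sweep_seed = int(self.rng.integers(2**31))
            self.A, self.V, acc_v, acc_b, acc_f = mc.sweep(
                m.verts, m.tris, m.e_v, m.e_t, m.tri_edge, m.nbr, m.nnbr,
                m.v_tri, m.nvt, fil_flat, n_beads, r0_arr,
                cfg.k_bond, cfg.k_angle, cfg.k_rep, self.rc,
                KT_FACTOR * cfg.kappa, cfg.sigma_kBT_um2,
                cfg.area_modulus, cfg.volume_modulus,
                m.area_target, m.volume_target, self.A, self.V,
                m.l_min**2, m.l_max**2, self.delta, n_flip, sweep_seed)
            if self.filaments is not None:
                self.filaments.positions = fil_flat.reshape(
                    self.filaments.positions.shape)
            self.t_sweeps += 1
            rate = acc_v / m.n_vertices
            self._acc_hist.append(rate)
            if tune and len(self._acc_hist) % 50 == 0:
                r = float(np.mean(self._acc_hist[-50:]))
                if not 0.2 <= r <= 0.7:
                    old = self.delta
                    self.delta = float(np.clip(
                        self.delta * (1.25 if r > 0.7 else 0.8),
                        1e-3, m.l_max))
                    warnings.warn(
                        f"vertex acceptance {r:.2f} outside [0.2, 0.7]; "
                        f"delta {old:.3f} -> {self.delta:.3f}")
        # refresh exact area/volume to kill incremental drift
        self.A = total_area(m.verts, m.tris)
        self.V = total_volume(m.verts, m.tris)

    # -- measurement --------------------------------------------------------

    def equatorial_contour(self, m_phi: int = 180) -> np.ndarray:
        c = self.mesh.verts.mean(axis=0)
        return mc.raycast_contour(self.mesh.verts, self.mesh.tris, c, m_phi)

    def vertex_forces(self) -> np.ndarray:
        if self.filaments is None:
            return np.zeros_like(self.mesh.verts)
        return mc.active_forces(self.mesh.verts,
                                self.filaments.positions.reshape(-1, 3),
                                self.config.k_rep, self.rc)

    def angular_force_profile(self, m_phi: int = 72,
                              z_band: float = 0.1) -> np.ndarray:
        """Radial force component binned in phi for vertices near z = 0."""
        f = self.vertex_forces()
        c = self.mesh.verts.mean(axis=0)
        rel = self.mesh.verts - c
        R0 = float(np.linalg.norm(rel, axis=1).mean())
        band = np.abs(rel[:, 2]) < z_band * R0
        prof = np.zeros(m_phi)
        cnt = np.zeros(m_phi)
        phis = np.mod(np.arctan2(rel[band, 1], rel[band, 0]), 2 * np.pi)
        rxy = np.linalg.norm(rel[band, :2], axis=1)
        fr = (f[band, 0] * rel[band, 0] + f[band, 1] * rel[band, 1]) \
            / np.maximum(rxy, 1e-12)
        idx = np.minimum((phis / (2 * np.pi) * m_phi).astype(int), m_phi - 1)
        np.add.at(prof, idx, fr)
        np.add.at(cnt, idx, 1.0)
        with np.errstate(invalid="ignore"):
            prof = np.where(cnt > 0, prof / np.maximum(cnt, 1), 0.0)
        return prof


def run_trajectory(sim: VesicleSim, n_snapshots: int, sweeps_per_snapshot: int,
                   equilibration_sweeps: int = 0, m_phi: int = 180,
                   measure_forces: bool = False):
    """Advance the simulation and collect contour (and force) snapshots.

    Returns a dict with 'contours' (n_snapshots, m_phi), 'forces'
    (optional angular profiles), 'area', 'volume' traces and the count of
    flagged frames (rays missing the mesh)."""
    if equilibration_sweeps:
        sim.step_dynamics(equilibration_sweeps)
    radii = np.empty((n_snapshots, m_phi))
    forces = np.empty((n_snapshots, 72)) if measure_forces else None
    area = np.empty(n_snapshots)
    vol = np.empty(n_snapshots)
    mean_f = np.empty(n_snapshots)
    flagged = 0
    for k in range(n_snapshots):
        sim.step_dynamics(sweeps_per_snapshot, tune=False)
        r = sim.equatorial_contour(m_phi)
        if np.any(~np.isfinite(r)):
            flagged += 1
            good = np.isfinite(r)
            phi = phi_grid(m_phi)
            r = np.interp(phi, phi[good], r[good], period=2 * np.pi)
        radii[k] = r
        area[k] = sim.A
        vol[k] = sim.V
        if measure_forces:
            forces[k] = sim.angular_force_profile()
            f = sim.vertex_forces()
            mean_f[k] = float(np.linalg.norm(f, axis=1).mean())
        else:
            mean_f[k] = 0.0
    return {"radii": radii, "forces": forces, "area": area, "volume": vol,
            "mean_force": mean_f, "flagged": flagged}


def measure(traj: dict, dt: float, q_max: int = 12,
            temperature: float = 300.0, R0_um: float | None = None,
            fit_range: tuple = (3, 10)) -> SimMeasurement:
    """Spectral measurement of a collected trajectory.

    ``dt`` is the snapshot interval (sweeps, or seconds after time
    calibration).  kappa and the effective tension come from the exact
    quasi-spherical equatorial fit; sigma_act = sigma_bar_hat *
    kappa_hat * kBT / R0^2 is the effective tension felt by the
    equatorial modes (constraint tension plus any active contribution).
    """
    from ..spectral import decompose_contour, fit_helfrich_equatorial, \
        fluctuation_spectrum

    phi = phi_grid(traj["radii"].shape[1])
    contours = ContourSeries(phi=phi, radii=traj["radii"], dt=dt)
    modes = decompose_contour(contours, q_max=q_max)
    spec = fluctuation_spectrum(modes, n_blocks=10)
    R0 = R0_um if R0_um is not None else contours.R0
    fit = fit_helfrich_equatorial(spec, R0=R0, temperature=temperature,
                                  fit_range=fit_range)
    force_modes = None
    if traj["forces"] is not None:
        force_modes = decompose_contour(
            traj["forces"], q_max=q_max, phi=phi_grid(traj["forces"].shape[1]),
            dt=dt, normalize=False)
    return SimMeasurement(
        contours=contours, force_modes=force_modes,
        mean_force=float(traj["mean_force"].mean()),
        sigma_act_SI=fit.sigma_hat, kappa_hat=fit.kappa_hat,
        sigma_bar_hat=fit.sigma_bar_hat, area_trace=traj["area"],
        volume_trace=traj["volume"], flagged_frames=traj["flagged"])


def calibrate_timescale(passive_traj_modes: ModeTrajectory,
                        params: MembraneParams, q_ref: int = 3) -> float:
    """Seconds per sweep, by matching the measured passive correlation
    time of mode ``q_ref`` (in sweeps) to the physical tau_q of
    ``params``.  Fails loudly when the mode never decorrelates within
    the trajectory."""
    from ..spectral import correlation_times

    ct = correlation_times(passive_traj_modes)
    i = np.flatnonzero(ct.q_values == q_ref)
    if i.size == 0 or not np.isfinite(ct.tau[i[0]]):
        raise RuntimeError(
            f"tau_{q_ref} unresolved: run a longer passive trajectory")
    tau_sweeps = float(ct.tau[i[0]])  # modes.dt is in sweeps here
    tau_phys = float(params.relaxation_time(q_ref))
    return tau_phys / tau_sweeps  # seconds per sweep
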