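"""In-memory containers shared by the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Number of angular samples on the internal uniform grid, phi in [0, 2pi),
#: counterclockwise, phi = 0 along +x.
M_PHI = 360

#: Fourier convention tag: R(phi)/R0 = 1 + sum_q [u_q e^{i q phi} + c.c.],
#: u_q = (b_q - i a_q) / (2 R0) for the cosine/sine quadrature amplitudes
#: b_q = (1/pi) int R cos(q phi) dphi, a_q = (1/pi) int R sin(q phi) dphi.
CONVENTION = "half-amplitude; u_q=(b_q-i*a_q)/(2*R0); R=R0(1+sum u_q e^{iq phi}+c.c.)"


def phi_grid(m: int = M_PHI) -> np.ndarray:
    return np.arange(m) * (2.0 * np.pi / m)


@dataclass
class ContourSeries:
    """Sampled equatorial radii R(phi_i, t_k) in micrometres."""

    phi: np.ndarray  # (M,) radians, uniform, [0, 2pi)
    radii: np.ndarray  # (n_frames, M) um
    dt: float  # s
    center: Optional[np.ndarray] = None  # (n_frames, 2) um

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.radii = np.atleast_2d(np.asarray(self.radii, dtype=float))
        if self.radii.shape[1] != self.phi.shape[0]:
            raise ValueError("radii and phi grids disagree")
        if np.any(np.diff(self.phi) <= 0):
            raise ValueError("phi must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.radii.shape[0]

    @property
    def R0(self) -> float:
        """Mean radius over phi and t."""
        return float(np.nanmean(self.radii))

    @property
    def deformation(self) -> np.ndarray:
        """Delta R = R - R0, same shape as radii."""
        return self.radii - self.R0


@dataclass
class ModeTrajectory:
    """Complex Fourier coefficients u_q(t), dimensionless (normalized by R0)."""

    q_values: np.ndarray  # (n_q,) ints, 1..q_max
    coefficients: np.ndarray  # (n_frames, n_q) complex
    dt: float  # s
    R0: float = 1.0  # um
    convention: str = CONVENTION

    def __post_init__(self) -> None:
        self.q_values = np.asarray(self.q_values, dtype=int)
        self.coefficients = np.atleast_2d(np.asarray(self.coefficients, dtype=complex))
        if self.coefficients.shape[1] != self.q_values.shape[0]:
            raise ValueError("coefficient columns must match q_values")

    @property
    def n_frames(self) -> int:
        return self.coefficients.shape[0]

    def mode(self, q: int) -> np.ndarray:
        idx = np.flatnonzero(self.q_values == q)
        if idx.size == 0:
            raise KeyError(f"mode q={q} not present")
        return self.coefficients[:, idx[0]]


@dataclass
class DensityField:
    """Angular microtubule intensity rho(phi_i, t_k), arbitrary units."""

    phi: np.ndarray
    rho: np.ndarray  # (n_frames, M)
    dt: float
    radial_profile: Optional[np.ndarray] = None  # (n_r, 2): r/R0, intensity

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.rho = np.atleast_2d(np.asarray(self.rho, dtype=float))
        if self.rho.shape[1] != self.phi.shape[0]:
            raise ValueError("rho and phi grids disagree")

    @property
    def n_frames(self) -> int:
        return self.rho.shape[0]


@dataclass
class SyntheticRecord:
    """Ground-truth bundle produced by the synthetic generators."""

    contour: ContourSeries
    density: Optional[DensityField]
    mode_truth: ModeTrajectory
    membrane: "object"  # MembraneParams
    active: Optional["object"] = None  # ActiveNoiseParams
    seed: Optional[int] = None


@dataclass
class SpectrumResult:
    """Per-mode time variance of the complex coefficients."""

    q_values: np.ndarray
    power: np.ndarray
    sem: np.ndarray  # NaN where undefined
    n_frames: int


@dataclass
class CorrelationTimes:
    """1/e-crossing correlation times per mode; NaN where undefined."""

    q_values: np.ndarray
    tau: np.ndarray
    definition: str = "first down-crossing of 1/e, linear interpolation"
    correlation_curves: Optional[np.ndarray] = None  # (n_q, n_lags)
    lags: Optional[np.ndarray] = None


@dataclass
class HelfrichFit:
    """Result of the equatorial Canham-Helfrich spectrum fit."""

    kappa_hat: float  # k_BT
    sigma_bar_hat: float  # dimensionless
    sigma_hat: float  # N/m
    kappa_err: float
    sigma_bar_err: float
    fit_range: tuple
    residuals: np.ndarray
    covariance: np.ndarray
    tension_below_resolution: bool = False


@dataclass
class KurtosisResult:
    """Excess kurtosis of pooled radial deformations per averaging window."""

    tau_avg_values: np.ndarray  # s
    mean: np.ndarray
    sd: np.ndarray
    min: np.ndarray
    max: np.ndarray
    variance: np.ndarray  # mean variance of dR/R0 per window


@dataclass
class FlowField:
    """Tangential/radial flow decomposition near the membrane."""

    phi: np.ndarray
    t: np.ndarray  # window centre times, s
    v_tangential: np.ndarray  # (n_windows, M) um/s, CCW positive
    v_radial: np.ndarray  # (n_windows, M) um/s
    averaging_window: float  # s
    tangential_fraction: float = np.nan  # <|v_T|> / <sqrt(v_T^2+v_r^2)>


@dataclass
class PhasePortrait:
    """Coarse-grained occupancy and edge currents for one coordinate pair."""

    labels: tuple
    x_edges: np.ndarray  # (nx+1,)
    y_edges: np.ndarray  # (ny+1,)
    occupancy: np.ndarray  # (nx, ny), time fraction
    jx: np.ndarray  # (nx-1, ny) net current box (i,j)->(i+1,j), 1/s
    jy: np.ndarray  # (nx, ny-1) net current box (i,j)->(i,j+1), 1/s
    n_transitions: int
    nonadjacent_fraction: float  # fraction of steps jumping >1 box


@dataclass
class FluxResult:
    """Normalized loop fluxes Omega over elementary plaquettes."""

    omega_per_cycle: np.ndarray
    mean_omega: float
    sd_omega: float
    z_score: float
    n_transitions: int
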