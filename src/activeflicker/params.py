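"""Physical parameter sets for membrane and active-noise models.

Units follow the package convention: lengths in micrometres, times in
seconds, bending rigidity in units of k_BT, tension in N/m (SI), viscosity
in Pa s.  The reduced tension ``sigma_bar = sigma R0^2 / (kappa k_BT)`` is
the single dimensionless number that decides whether equatorial
fluctuations are bending- (q^-3) or tension- (q^-1) dominated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: Boltzmann constant, J/K.
KB = 1.380649e-23

#: Convention factor in the equatorial mode-variance formula
#: <|u_q|^2> = C_CONV * (k_BT/kappa) / (q^3 + sigma_bar q).
#: With the half-amplitude convention u_q = (b_q - i a_q)/(2 R0) used
#: throughout this package, C_CONV = 1/2 makes generation and fitting
#: self-consistent (parameter recovery is what the tests assert).
C_CONV = 0.5


@dataclass(frozen=True)
class MembraneParams:
    """Quasi-spherical membrane parameters.

    Parameters
    ----------
    kappa : float
        Bending rigidity in units of k_BT.
    sigma : float
        Membrane tension in N/m.
    R0 : float
        Mean vesicle radius in micrometres.
    temperature : float
        Absolute temperature in kelvin.
    eta : float
        Effective solvent viscosity in Pa s; sets the absolute scale of
        the passive relaxation times ``tau_q = 4 eta R0^3 / (kappa_SI
        (q^3 + sigma_bar q))``.
    """

    kappa: float = 13.4
    sigma: float = 0.0
    R0: float = 25.0
    temperature: float = 300.0
    eta: float = 1.0e-3

    def __post_init__(self) -> None:
        for name in ("kappa", "sigma", "R0", "temperature", "eta"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.R0 <= 0:
            raise ValueError("R0 must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def kBT(self) -> float:
        """Thermal energy in joules."""
        return KB * self.temperature

    @property
    def kappa_SI(self) -> float:
        """Bending rigidity in joules."""
        return self.kappa * self.kBT

    @property
    def sigma_bar(self) -> float:
        """Reduced (dimensionless) tension sigma R0^2 / (kappa k_BT)."""
        R0_m = self.R0 * 1e-6
        return self.sigma * R0_m**2 / self.kappa_SI

    def mode_variance(self, q) -> "float | object":
        """Prescribed stationary variance <|u_q|^2> of mode q."""
        import numpy as np

        q = np.asarray(q, dtype=float)
        return C_CONV * (1.0 / self.kappa) / (q**3 + self.sigma_bar * q)

    def relaxation_time(self, q) -> "float | object":
        """Passive relaxation time tau_q^P in seconds."""
        import numpy as np

        q = np.asarray(q, dtype=float)
        R0_m = self.R0 * 1e-6
        return 4.0 * self.eta * R0_m**3 / (self.kappa_SI * (q**3 + self.sigma_bar * q))


@dataclass(frozen=True)
class ActiveNoiseParams:
    """Travelling density-bump model of cytoskeletal activity.

    Bumps of microtubule density are born at ``birth_rate`` per second,
    live for an exponentially distributed time of mean ``lifetime_Ta``,
    and are advected tangentially at speed ``speed_v`` (angular speed
    omega = v/R0), each carrying a co-moving membrane deformation whose
    mode content follows ``q**(spectrum_exponent/2)``.

    The default lifetime is long compared with the advective
    decorrelation time so that the correlation times of the deformation
    modes are set by transport, tau_q ~ 1/(q omega) -- the regime in
    which travelling deformations produce the q^-1 scaling of
    correlation times.  The measured deformation correlation time at low
    q is then of order 10 s for v = 1 um/s on a 25 um vesicle.
    """

    speed_v: float = 1.0  # um/s along the membrane
    lifetime_Ta: float = 100.0  # s, mean bump lifetime
    birth_rate: float = 0.15  # bumps per second (mean population = rate * Ta)
    width_w: float = 0.4  # rad, angular extent of the density bump
    amplitude: float = 0.08  # peak fractional deformation of one bump
    spectrum_exponent: float = -3.0  # power law of the bump deformation spectrum
    direction_switching: float = 0.5  # probability a bump travels CCW

    def __post_init__(self) -> None:
        if self.speed_v < 0:
            raise ValueError("speed_v must be >= 0")
        if self.lifetime_Ta <= 0:
            raise ValueError("lifetime_Ta must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0.0 <= self.direction_switching <= 1.0:
            raise ValueError("direction_switching must be in [0, 1]")
        if self.birth_rate < 0:
            raise ValueError("birth_rate must be >= 0")
        if self.width_w <= 0:
            raise ValueError("width_w must be > 0")
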