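"""Bead-spring filaments with triangle-wave extension/retraction.

Each filament is a chain of ``n_beads`` beads with harmonic bonds whose
rest length grows linearly so that the total rest length goes from L to
L_max over T_str, then shrinks back over T_str (a triangle wave).  On
completing a shrink phase the filament is re-seeded at a random interior
position with a random orientation, standing in for bundles breaking or
detaching from the membrane.  Per-filament phase offsets are randomized
at initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class FilamentSet:
    positions: np.ndarray  # (n_fil, n_beads, 3) um
    n_beads: int
    L: float  # relaxed total rest length, um
    L_max: float  # maximal total rest length, um
    T_str: float  # growth (and shrink) duration, in sweeps or seconds
    phase_offsets: np.ndarray  # (n_fil,) in [0, 2 T_str)
    bending_stiffness: float = 500.0  # kBT per (1 - cos) unit

    @property
    def n_fil(self) -> int:
        return self.positions.shape[0]

    def rest_length_total(self, t: float) -> np.ndarray:
        """Total rest length of each filament at time t (triangle wave)."""
        tau = np.mod(t + self.phase_offsets, 2.0 * self.T_str) \
            if np.isfinite(self.T_str) else np.zeros(self.n_fil)
        frac = np.where(tau < self.T_str, tau / self.T_str,
                        2.0 - tau / self.T_str)
        return self.L + (self.L_max - self.L) * frac

    def rest_bond_length(self, t: float) -> np.ndarray:
        return self.rest_length_total(t) / (self.n_beads - 1)


def _straight_chain(rng, n_beads, spacing, r_center_max):
    c = rng.uniform(-1, 1, 3)
    c *= r_center_max * rng.uniform(0, 1) ** (1 / 3) / max(np.linalg.norm(c), 1e-12)
    d = rng.standard_normal(3)
    d /= np.linalg.norm(d)
    s = (np.arange(n_beads) - (n_beads - 1) / 2) * spacing
    return c[None, :] + s[:, None] * d[None, :]


def init_filaments(n_fil: int, n_beads: int, L: float, L_max: float,
                   T_str: float, vesicle_radius: float, seed: int = 0,
                   bending_stiffness: float = 500.0) -> FilamentSet:
    """Straight chains at the relaxed length, placed randomly inside the
    vesicle so that no endpoint starts outside the membrane."""
    rng = np.random.default_rng(seed)
    spacing = L / (n_beads - 1)
    margin = max(vesicle_radius - L / 2.0 - spacing, 0.1 * vesicle_radius)
    pos = np.stack([_straight_chain(rng, n_beads, spacing, margin)
                    for _ in range(n_fil)])
    offsets = rng.uniform(0.0, 2.0 * T_str, n_fil) if np.isfinite(T_str) \
        else np.zeros(n_fil)
    return FilamentSet(positions=pos, n_beads=n_beads, L=L, L_max=L_max,
                       T_str=T_str, phase_offsets=offsets,
                       bending_stiffness=bending_stiffness)


def growth_update(filaments: FilamentSet, t_prev: float, t_now: float,
                  vesicle_radius: float, rng: np.random.Generator) -> np.ndarray:
    """Advance the growth clock; re-seed filaments that completed a
    shrink phase between t_prev and t_now.  Returns the rest bond length
    per filament at t_now."""
    if np.isfinite(filaments.T_str) and t_now > t_prev:
        period = 2.0 * filaments.T_str
        k_prev = np.floor((t_prev + filaments.phase_offsets) / period)
        k_now = np.floor((t_now + filaments.phase_offsets) / period)
        for f in np.flatnonzero(k_now > k_prev):
            spacing = filaments.L / (filaments.n_beads - 1)
            margin = max(vesicle_radius - filaments.L / 2.0 - spacing,
                         0.1 * vesicle_radius)
            filaments.positions[f] = _straight_chain(
                rng, filaments.n_beads, spacing, margin)
    return filaments.rest_bond_length(t_now)
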