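"""File formats: delimited tables, TIFF stacks and the HDF5 container.

Conventions stated in every header: angles in radians, lengths in
micrometres, times in seconds.  The HDF5 container uses fixed groups
/contour, /density, /modes and /params; unknown extra groups are
accepted with a warning (forward compatibility).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .containers import ContourSeries, DensityField, ModeTrajectory, CONVENTION

_KNOWN_GROUPS = {"contour", "density", "modes", "params"}


# ---------------------------------------------------------------------------
# Delimited text
# ---------------------------------------------------------------------------

def write_contour_table(path, contour: ContourSeries) -> None:
    """Rows = frames, columns = phi samples; phi grid in the header."""
    path = Path(path)
    header = ("angles phi in radians (columns); one frame per row; radii in um; "
              f"dt = {contour.dt} s\n" + " ".join(f"{p:.10g}" for p in contour.phi))
    np.savetxt(path, contour.radii, header=header)


def read_contour_table(path, dt: float | None = None) -> ContourSeries:
    path = Path(path)
    with open(path) as fh:
        lines = []
        for line in fh:
            if line.startswith("#"):
                lines.append(line[1:].strip())
            else:
                break
    if len(lines) < 2:
        raise ValueError(
            f"{path}: expected a 2-line header (description + phi grid), "
            f"found {len(lines)} comment lines")
    if dt is None:
        try:
            dt = float(lines[0].split("dt =")[1].split("s")[0])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}: cannot parse dt from header") from exc
    phi = np.array([float(x) for x in lines[-1].split()])
    radii = np.loadtxt(path)
    return ContourSeries(phi=phi, radii=np.atleast_2d(radii), dt=dt)


def write_density_table(path, density: DensityField) -> None:
    header = ("angles phi in radians (columns); one frame per row; intensity a.u.; "
              f"dt = {density.dt} s\n" + " ".join(f"{p:.10g}" for p in density.phi))
    np.savetxt(Path(path), density.rho, header=header)


def write_modes_table(path, modes: ModeTrajectory) -> None:
    """Columns: Re u_1, Im u_1, Re u_2, ... ; q list in the header."""
    u = modes.coefficients
    out = np.empty((u.shape[0], 2 * u.shape[1]))
    out[:, 0::2] = u.real
    out[:, 1::2] = u.imag
    header = (f"complex mode coefficients, dimensionless; dt = {modes.dt} s; "
              f"R0 = {modes.R0} um; convention: {modes.convention}\n"
              "q = " + " ".join(str(q) for q in modes.q_values))
    np.savetxt(Path(path), out, header=header)


def write_spectrum_table(path, spectrum) -> None:
    arr = np.column_stack([spectrum.q_values, spectrum.power, spectrum.sem])
    np.savetxt(Path(path), arr, header="q  power<|u_q|^2>  sem")


def write_times_table(path, times) -> None:
    arr = np.column_stack([times.q_values, times.tau])
    np.savetxt(Path(path), arr, header="q  tau_q (s, 1/e crossing; nan=undefined)")


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------

def write_stack(path, stack: np.ndarray, pixel_size: float | None = None) -> None:
    """Multi-page TIFF, page order = time."""
    meta = {"axes": "TYX"}
    if pixel_size is not None:
        meta["pixel_size_um"] = pixel_size
    tifffile.imwrite(Path(path), np.asarray(stack, dtype=np.float32),
                     metadata=meta)


def read_stack(path) -> np.ndarray:
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # truncated / invalid file: no partial results
        raise OSError(f"cannot read TIFF stack {path}: {exc}") from exc
    return np.atleast_3d(arr)


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def save_container(path, contour: ContourSeries | None = None,
                   density: DensityField | None = None,
                   modes: ModeTrajectory | None = None,
                   params: dict | None = None) -> None:
    with h5py.File(Path(path), "w") as f:
        f.attrs["units"] = "phi: rad; lengths: um; times: s"
        if contour is not None:
            g = f.create_group("contour")
            g.create_dataset("phi", data=contour.phi)
            g.create_dataset("radii", data=contour.radii)
            g.attrs["dt"] = contour.dt
            if contour.center is not None:
                g.create_dataset("center", data=contour.center)
        if density is not None:
            g = f.create_group("density")
            g.create_dataset("phi", data=density.phi)
            g.create_dataset("rho", data=density.rho)
            g.attrs["dt"] = density.dt
            if density.radial_profile is not None:
                g.create_dataset("radial_profile", data=density.radial_profile)
        if modes is not None:
            g = f.create_group("modes")
            g.create_dataset("q", data=modes.q_values)
            g.create_dataset("coefficients", data=modes.coefficients)
            g.attrs["dt"] = modes.dt
            g.attrs["R0"] = modes.R0
            g.attrs["convention"] = modes.convention
        if params is not None:
            g = f.create_group("params")
            g.attrs["json"] = json.dumps(params, default=str)


def load_container(path) -> dict:
    """Load whatever groups the container holds; warns on unknown groups."""
    out = {}
    with h5py.File(Path(path), "r") as f:
        extra = set(f.keys()) - _KNOWN_GROUPS
        if extra:
            warnings.warn(f"container has unknown extra groups {sorted(extra)}; "
                          "ignored for forward compatibility")
        if "contour" in f:
            g = f["contour"]
            out["contour"] = ContourSeries(
                phi=g["phi"][()], radii=g["radii"][()], dt=float(g.attrs["dt"]),
                center=g["center"][()] if "center" in g else None)
        if "density" in f:
            g = f["density"]
            out["density"] = DensityField(
                phi=g["phi"][()], rho=g["rho"][()], dt=float(g.attrs["dt"]),
                radial_profile=g["radial_profile"][()]
                if "radial_profile" in g else None)
        if "modes" in f:
            g = f["modes"]
            out["modes"] = ModeTrajectory(
                q_values=g["q"][()], coefficients=g["coefficients"][()],
                dt=float(g.attrs["dt"]), R0=float(g.attrs["R0"]),
                convention=str(g.attrs["convention"]))
        if "params" in f:
            out["params"] = json.loads(f["params"].attrs["json"])
    return out


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

def write_manifest(path, command: str, config: dict, seed: int | None,
                   inputs: dict | None = None) -> None:
    import datetime
    from . import __version__

    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "inputs": inputs or {},
        "version": __version__,
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
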