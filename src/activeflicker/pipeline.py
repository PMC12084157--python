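"""End-to-end workflow: source -> modes -> spectra -> times -> kurtosis -> flux.

The pipeline consumes a configuration dict naming a source (synthetic
preset, 3D simulation, a TIFF stack or a saved container) and emits a
report dict plus delimited tables and a run manifest in the output
directory.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np

from . import io as afio
from .containers import ContourSeries, DensityField
from .extract import ExtractionConfig, extract_stack
from .flux import mode_pair_scan
from .params import ActiveNoiseParams, MembraneParams
from .spectral import (
    correlation_times,
    decompose_contour,
    fit_helfrich,
    fit_powerlaw,
    fluctuation_spectrum,
    kurtosis_analysis,
)
from .synthetic import simulate_active_record, passive_contour

log = logging.getLogger("activeflicker")

DEFAULT_PAIRS = [(2, 2), (3, 3), (2, 3), (3, 4)]


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            t0 = time.perf_counter()
            try:
                out = fn(*a, **k)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            log.info("stage %-10s %.2f s", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("source")
def _load_source(config: dict, seed: int):
    src = config.get("source", "passive")
    dt = float(config.get("dt", 0.2))
    n_steps = int(config.get("n_steps", 3000))
    if src == "passive":
        mp = MembraneParams(**config.get("membrane", {}))
        rec = passive_contour(mp, dt=dt, n_steps=n_steps, seed=seed)
        return rec.contour, None, rec
    if src == "active":
        mp = MembraneParams(**config.get("membrane", {}))
        ap = ActiveNoiseParams(**config.get("active", {}))
        rec = simulate_active_record(mp, ap, dt=dt, n_steps=n_steps, seed=seed)
        return rec.contour, rec.density, rec
    if src == "container":
        data = afio.load_container(config["path"])
        return data["contour"], data.get("density"), None
    if src == "tiff":
        path = Path(config["path"])
        if not path.exists():
            raise FileNotFoundError(f"input stack not found: {path}")
        stack = afio.read_stack(path)
        mt = None
        if config.get("mt_path"):
            mt = afio.read_stack(config["mt_path"])
        exc = ExtractionConfig(**config.get("extraction", {}))
        contours, density, n_rej = extract_stack(stack, exc, dt=dt, mt_stack=mt)
        log.info("extraction rejected %d frames", n_rej)
        return contours, density, None
    raise ValueError(f"unknown source {src!r}")


def run_pipeline(config: dict, seed: int = 0, out_dir=None) -> dict:
    """Execute the full analysis chain and return the report dict."""
    contours, density, rec = _load_source(config, seed)
    q_max = int(config.get("q_max", 15))
    modes = decompose_contour(contours, q_max=q_max)
    spec = fluctuation_spectrum(modes)
    fit = fit_helfrich(spec, R0=contours.R0,
                       fit_range=tuple(config.get("fit_range", (3, q_max))))
    sl_spec, sl_spec_err = fit_powerlaw(spec.q_values, spec.power, (3, min(12, q_max)))
    times = correlation_times(modes)
    tmask = np.isfinite(times.tau) & (times.q_values >= 2) & (times.q_values <= 8)
    if tmask.sum() >= 3:
        sl_tau, sl_tau_err = fit_powerlaw(times.q_values[tmask], times.tau[tmask])
    else:
        sl_tau, sl_tau_err = np.nan, np.nan
    kur = kurtosis_analysis(contours, config.get("tau_avg", [2.0, 5.0, 10.0]))
    pairs = [tuple(p) for p in config.get("flux_pairs", DEFAULT_PAIRS)]
    scan = mode_pair_scan(modes, pairs, coordinate="complex")
    report = {
        "R0_um": contours.R0,
        "n_frames": contours.n_frames,
        "kappa_hat_kBT": fit.kappa_hat,
        "sigma_hat_N_per_m": fit.sigma_hat,
        "sigma_bar_hat": fit.sigma_bar_hat,
        "spectrum_exponent": sl_spec,
        "spectrum_exponent_err": sl_spec_err,
        "tau_exponent": sl_tau,
        "tau_exponent_err": sl_tau_err,
        "kurtosis": {float(t): float(m) for t, m in
                     zip(kur.tau_avg_values, kur.mean)},
        "flux": [{"pair": list(r["pair"]), "z": r["z"],
                  "significant": r["significant"]} for r in scan],
        "broken_detailed_balance": any(r["significant"] for r in scan),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        afio.write_contour_table(out_dir / "contours.txt", contours)
        afio.write_modes_table(out_dir / "modes.txt", modes)
        afio.write_spectrum_table(out_dir / "spectrum.txt", spec)
        afio.write_times_table(out_dir / "times.txt", times)
        if density is not None:
            afio.write_density_table(out_dir / "density.txt", density)
        afio.save_container(out_dir / "record.h5", contour=contours,
                            density=density, modes=modes,
                            params={"config": config, "seed": seed})
        import json

        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, default=float) + "\n")
        afio.write_manifest(out_dir / "manifest.json", "report", config, seed)
    return report
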