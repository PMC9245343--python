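"""Plain-text interchange formats: TSV traces/trajectories, YAML configs.

Everything on disk is SI (seconds, metres, amperes); the CLI converts
to nm/ms/pA only in human-facing summaries.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import PoreTrajectory, VesicleGeometry
from .model import CurrentTrace, SimulationConfig, TransportParams
from .reconstruction import ReconstructionConfig
from .spikes import Spike
from .synthetic import SynthSpec

__all__ = [
    "write_trace", "read_trace", "read_spike",
    "write_trajectory", "read_trajectory",
    "write_population", "read_population",
    "load_run_config", "write_manifest",
]

_TRACE_COLS = ["time_s", "current_A"]
_TRAJ_COLS = ["time_s", "pore_radius_m"]


def write_trace(path, trace: CurrentTrace) -> None:
    df = pd.DataFrame({"time_s": trace.times, "current_A": trace.currents})
    df.to_csv(path, sep="\t", index=False)
    if trace.metadata:
        Path(str(path) + ".json").write_text(
            json.dumps(trace.metadata, indent=2, default=str))


def _read_tsv(path, required) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for c in required:
        if c != "group":
            df[c] = pd.to_numeric(df[c], errors="coerce")
    bad = df[required].isna().any(axis=1)
    if bad.any():
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # header + 1-based
        raise ValueError(f"{path}: malformed value at line {line}")
    return df


def read_trace(path) -> CurrentTrace:
    df = _read_tsv(path, _TRACE_COLS)
    return CurrentTrace(df["time_s"].to_numpy(float),
                        df["current_A"].to_numpy(float))


def read_spike(path, baseline_sd: float = 0.0) -> Spike:
    df = _read_tsv(path, _TRACE_COLS)
    return Spike(df["time_s"].to_numpy(float), df["current_A"].to_numpy(float),
                 baseline_sd=baseline_sd, metadata={"source": str(path)})


def write_trajectory(path, traj: PoreTrajectory, flags=None) -> None:
    df = pd.DataFrame({"time_s": traj.times, "pore_radius_m": traj.radii})
    if flags is not None:
        df["flag"] = list(flags)
    df.to_csv(path, sep="\t", index=False)


def read_trajectory(path) -> PoreTrajectory:
    df = _read_tsv(path, _TRAJ_COLS)
    return PoreTrajectory(df["time_s"].to_numpy(float),
                          df["pore_radius_m"].to_numpy(float))


def write_population(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_population(path) -> pd.DataFrame:
    return _read_tsv(path, ["rves_m", "rpmax_m"])


# --------------------------------------------------------------- run config

_GEOMETRY_KEYS = {"vesicle_radius_nm", "pore_length_nm", "gap_nm",
                  "electrode_radius_um", "domain_radius_um", "domain_height_um"}
_TRANSPORT_KEYS = {"d_in_m2_s", "d_out_m2_s", "n_electrons"}
_RECON_KEYS = {"dt_ms", "lower_bound_nm", "upper_factor", "xatol_nm",
               "r_initial_nm", "backend", "n_substeps", "depletion_cutoff"}
_SIM_KEYS = {"axis_cell_nm", "growth", "dt_us", "n_gap_cells",
             "n_membrane_cells"}
_SYNTH_KEYS = {"rves_median_nm", "rves_log_sd", "q_median_pC", "q_log_sd",
               "r_max_nm", "t50_ms", "steepness_ms", "t_end_ms",
               "sample_dt_ms", "noise_sd_frac", "scaling_slope",
               "scaling_intercept", "scaling_scatter", "seed"}
_SECTIONS = {"geometry", "transport", "reconstruction", "simulation", "synth",
             "charge_pC"}


def _check_keys(section: str, given: dict, allowed: set) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {section!r}: {sorted(unknown)}")


def load_run_config(path) -> dict:
    """Parse a YAML run configuration into typed objects.

    Recognized sections: ``geometry``, ``transport``, ``reconstruction``,
    ``simulation``, ``synth``, ``charge_pC``.  Unknown keys anywhere are
    rejected.  Returns a dict with the corresponding dataclass
    instances (absent sections use package defaults).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    _check_keys("run config", raw, _SECTIONS)
    out: dict = {}

    geo = raw.get("geometry", {})
    _check_keys("geometry", geo, _GEOMETRY_KEYS)
    if "vesicle_radius_nm" in geo:
        out["geometry"] = VesicleGeometry(
            vesicle_radius=geo["vesicle_radius_nm"] * 1e-9,
            pore_length=geo.get("pore_length_nm", 5.0) * 1e-9,
            gap=geo.get("gap_nm", 20.0) * 1e-9,
            electrode_radius=geo.get("electrode_radius_um", 2.5) * 1e-6,
            outer_domain_radius=geo.get("domain_radius_um", 0.0) * 1e-6,
            outer_domain_height=geo.get("domain_height_um", 2.0) * 1e-6,
        )

    tp = raw.get("transport", {})
    _check_keys("transport", tp, _TRANSPORT_KEYS)
    out["transport"] = TransportParams(
        d_in=tp.get("d_in_m2_s", 6.0e-11),
        d_out=tp.get("d_out_m2_s", 6.0e-10),
        n_electrons=tp.get("n_electrons", 2),
    )

    rc = raw.get("reconstruction", {})
    _check_keys("reconstruction", rc, _RECON_KEYS)
    out["reconstruction"] = ReconstructionConfig(
        dt=rc.get("dt_ms", 0.1) * 1e-3,
        lower_bound=rc.get("lower_bound_nm", 0.01) * 1e-9,
        upper_factor=rc.get("upper_factor", 0.8),
        xatol=rc.get("xatol_nm", 0.01) * 1e-9,
        r_initial=rc.get("r_initial_nm", 0.1) * 1e-9,
        backend=rc.get("backend", "quasi-steady"),
        n_substeps=rc.get("n_substeps", 10),
        depletion_cutoff=rc.get("depletion_cutoff", 0.95),
    )

    sc = raw.get("simulation", {})
    _check_keys("simulation", sc, _SIM_KEYS)
    out["simulation"] = SimulationConfig(
        axis_cell=sc.get("axis_cell_nm", 0.25) * 1e-9,
        growth=sc.get("growth", 1.2),
        dt=sc.get("dt_us", 10.0) * 1e-6,
        n_gap_cells=sc.get("n_gap_cells", 3),
        n_membrane_cells=sc.get("n_membrane_cells", 4),
    )

    sy = raw.get("synth", {})
    _check_keys("synth", sy, _SYNTH_KEYS)
    kwargs = {}
    scale = {"rves_median_nm": ("rves_median", 1e-9),
             "q_median_pC": ("q_median", 1e-12),
             "r_max_nm": ("r_max", 1e-9), "t50_ms": ("t50", 1e-3),
             "steepness_ms": ("steepness", 1e-3), "t_end_ms": ("t_end", 1e-3),
             "sample_dt_ms": ("sample_dt", 1e-3)}
    for key, val in sy.items():
        if key in scale:
            name, fac = scale[key]
            kwargs[name] = val * fac
        else:
            kwargs[key] = val
    out["synth"] = SynthSpec(**kwargs)

    if "charge_pC" in raw:
        out["charge"] = raw["charge_pC"] * 1e-12
    return out


def write_manifest(out_dir, seed, config_paths=(), extra=None) -> Path:
    """Reproducibility manifest: code version, seed, config hashes."""
    from . import __version__
    digest = {}
    for p in config_paths:
        p = Path(p)
        if p.exists():
            digest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    manifest = {"poretrace_version": __version__, "seed": seed,
                "config_sha256": digest}
    if extra:
        manifest.update(extra)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
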