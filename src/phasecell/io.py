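"""Configuration files, trajectory containers, and provenance.

Configs are YAML with three optional sections — ``model``, ``pattern``,
``ensemble``, ``inference`` — whose keys mirror the conventional parameter
names (``tau_f`` and ``tau_chi`` in seconds; every other time in minutes,
lengths in μm).  Unknown keys are rejected rather than silently ignored.
Trajectory ensembles round-trip through HDF5 (one group per run) and can
be exported to a flat CSV.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .params import ModelParams, Numerics, SECONDS_PER_MINUTE
from .micropattern import PatternSpec
from .simulate import Trajectory, TrajectorySet


class ConfigError(ValueError):
    """Malformed or inconsistent configuration file."""


#: model-section keys given in seconds (converted to minutes internally)
_SECONDS_KEYS = {"tau_f", "tau_chi"}
_MODEL_KEYS = {
    "gamma", "lam", "kappa", "R0", "eta", "M", "alpha", "mu_beta",
    "sigma_beta", "sigma", "s0", "tau_f", "tau_chi", "tau_s", "tau",
    "ell", "gamma0", "c_well", "no_filopodia", "no_chi_coupling",
    "no_perimeter_inhibition", "patch_mode",
}
_NUMERICS_KEYS = {"dx", "dt", "pad", "sample_interval", "eps_phi",
                  "grad_floor"}
_PATTERN_KEYS = {"kind", "basin_size", "bridge_height", "bridge_length",
                 "rect_width", "rect_height", "polygons", "smoothing"}
_ENSEMBLE_KEYS = {"n_runs", "duration", "base_seed", "init_mode"}
_INFERENCE_KEYS = {"dt_sample", "n_xbins", "n_vbins", "min_count",
                   "bootstrap"}


@dataclass
class RunConfig:
    """Validated configuration for a simulation + inference campaign."""

    params: ModelParams
    pattern: PatternSpec
    ensemble: dict = dataclass_field(default_factory=dict)
    inference: dict = dataclass_field(default_factory=dict)
    source_digest: str = ""

    def to_dict(self) -> dict:
        model = {}
        for k in sorted(_MODEL_KEYS):
            attr = getattr(self.params, k)
            if k in _SECONDS_KEYS:
                attr = attr * SECONDS_PER_MINUTE
            model[k] = attr
        numerics = {k: getattr(self.params.numerics, k)
                    for k in sorted(_NUMERICS_KEYS)}
        pattern = {k: getattr(self.pattern, k) for k in sorted(_PATTERN_KEYS)}
        return {"model": model, "numerics": numerics, "pattern": pattern,
                "ensemble": dict(self.ensemble),
                "inference": dict(self.inference)}


def _check_keys(section: dict, allowed: set, name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in [{name}]: {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}")


def config_from_dict(raw: dict, digest: str = "") -> RunConfig:
    """Build a validated RunConfig from a parsed mapping."""
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, {"model", "numerics", "pattern", "ensemble",
                      "inference"}, "root")
    model = dict(raw.get("model") or {})
    _check_keys(model, _MODEL_KEYS, "model")
    for k in _SECONDS_KEYS & set(model):
        model[k] = float(model[k]) / SECONDS_PER_MINUTE
    numerics = dict(raw.get("numerics") or {})
    _check_keys(numerics, _NUMERICS_KEYS, "numerics")
    pattern = dict(raw.get("pattern") or {})
    _check_keys(pattern, _PATTERN_KEYS, "pattern")
    if "polygons" in pattern:
        pattern["polygons"] = [[tuple(map(float, v)) for v in poly]
                               for poly in pattern["polygons"]]
    ensemble = dict(raw.get("ensemble") or {})
    _check_keys(ensemble, _ENSEMBLE_KEYS, "ensemble")
    inference = dict(raw.get("inference") or {})
    _check_keys(inference, _INFERENCE_KEYS, "inference")
    try:
        params = ModelParams(numerics=Numerics(**numerics), **model)
        spec = PatternSpec(**pattern)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return RunConfig(params=params, pattern=spec, ensemble=ensemble,
                     inference=inference, source_digest=digest)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; records the file's SHA-256."""
    path = Path(path)
    text = path.read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    try:
        raw = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return config_from_dict(raw, digest)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def params_digest(params: ModelParams) -> str:
    """Stable hash of the full parameter set (provenance guard)."""
    d = params.to_dict()
    blob = json.dumps(d, sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_trajectories(tset: TrajectorySet, path: str | Path) -> None:
    """Write an ensemble to HDF5: one group per run, flags as attributes."""
    with h5py.File(path, "w") as f:
        f.attrs["package_version"] = __version__
        f.attrs["params_hash"] = tset.params_hash
        f.attrs["pattern_kind"] = tset.pattern_kind
        f.attrs["meta"] = json.dumps(tset.meta, default=float)
        for i, run in enumerate(tset.runs):
            g = f.create_group(f"run{i:05d}")
            for name in ("times", "x", "y", "area", "perimeter"):
                g.create_dataset(name, data=getattr(run, name))
            g.attrs["seed"] = -1 if run.seed is None else run.seed
            g.attrs["ruptured"] = run.ruptured
            g.attrs["escaped"] = run.escaped
            g.attrs["failed"] = run.failed
            if run.patch_log is not None:
                g.create_dataset("patch_log", data=run.patch_log)


def read_trajectories(path: str | Path) -> TrajectorySet:
    """Inverse of :func:`write_trajectories` (lossless round-trip)."""
    runs = []
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs.get("meta", "{}"))
        params_hash = str(f.attrs.get("params_hash", ""))
        pattern_kind = str(f.attrs.get("pattern_kind", ""))
        for key in sorted(f.keys()):
            g = f[key]
            seed = int(g.attrs["seed"])
            runs.append(Trajectory(
                times=g["times"][...], x=g["x"][...], y=g["y"][...],
                area=g["area"][...], perimeter=g["perimeter"][...],
                seed=None if seed < 0 else seed,
                ruptured=bool(g.attrs["ruptured"]),
                escaped=bool(g.attrs["escaped"]),
                failed=bool(g.attrs["failed"]),
                patch_log=(g["patch_log"][...] if "patch_log" in g
                           else None)))
    return TrajectorySet(runs=runs, params_hash=params_hash,
                         pattern_kind=pattern_kind, meta=meta)


def write_field_snapshots(traj, path: str | Path) -> None:
    """Write per-sample ϕ and P snapshots of a run recorded with
    ``record_fields=True``: groups /phi and /P with one dataset per
    frame, and grid attributes dx, origin, t."""
    snapshots = getattr(traj, "fields", None)
    if snapshots is None:
        raise ValueError("trajectory was not recorded with record_fields")
    state = getattr(traj, "final_state", None)
    with h5py.File(path, "w") as f:
        f.attrs["package_version"] = __version__
        gp = f.create_group("phi")
        gP = f.create_group("P")
        for i, ((phi, P), t) in enumerate(zip(snapshots, traj.times)):
            for g, arr in ((gp, phi), (gP, P)):
                d = g.create_dataset(f"frame{i:05d}", data=arr)
                d.attrs["t"] = t
                if state is not None:
                    d.attrs["dx"] = state.phi.grid.dx
                    d.attrs["origin"] = state.phi.grid.origin


def read_field_snapshots(path: str | Path):
    """Inverse of :func:`write_field_snapshots`; returns (times, phis, Ps)."""
    with h5py.File(path, "r") as f:
        keys = sorted(f["phi"].keys())
        times = np.array([f["phi"][k].attrs["t"] for k in keys])
        phis = [f["phi"][k][...] for k in keys]
        Ps = [f["P"][k][...] for k in keys]
    return times, phis, Ps


def dwells_to_csv(stats, path: str | Path) -> None:
    """Flat CSV of per-run dwell durations (columns: run, dwell_min)."""
    rows = []
    for i, dwells in enumerate(stats.dwells_per_run):
        for d in dwells:
            rows.append({"run": i, "dwell_min": float(d)})
    pd.DataFrame(rows, columns=["run", "dwell_min"]).to_csv(path,
                                                            index=False)


def trajectories_to_csv(tset: TrajectorySet, path: str | Path) -> None:
    """Flat CSV export: run, t_min, x_um, y_um, area_um2, perim_um."""
    frames = []
    for i, run in enumerate(tset.runs):
        frames.append(pd.DataFrame({
            "run": i, "t_min": run.times, "x_um": run.x, "y_um": run.y,
            "area_um2": run.area, "perim_um": run.perimeter}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def merge_trajectory_sets(a: TrajectorySet, b: TrajectorySet
                          ) -> TrajectorySet:
    """Concatenate two ensembles; refuses on a parameter-hash mismatch."""
    if a.params_hash != b.params_hash:
        raise ValueError(
            f"params hash mismatch ({a.params_hash} != {b.params_hash}); "
            "refusing to merge ensembles with different parameters")
    meta = dict(a.meta)
    meta["merged"] = True
    return TrajectorySet(runs=list(a.runs) + list(b.runs),
                         params_hash=a.params_hash,
                         pattern_kind=a.pattern_kind, meta=meta)


def portrait_to_json(field, portrait, path: str | Path) -> None:
    """Serialize a drift field + labeled portrait to structured JSON."""
    doc = {
        "label": portrait.label,
        "x_edges": field.x_edges.tolist(),
        "v_edges": field.v_edges.tolist(),
        "F": [[None if not np.isfinite(v) else v for v in row]
              for row in field.F],
        "counts": field.counts.tolist(),
        "terminal_points": portrait.terminal_points.tolist(),
        "terminal_group": portrait.terminal_group.tolist(),
        "n_cycling": int(portrait.cycling.sum()),
        "separatrices": [s.tolist() for s in portrait.separatrices],
        "diagnostics": {
            k: v for k, v in portrait.diagnostics.items()
            if isinstance(v, (int, float, str, list))},
        "package_version": __version__,
    }
    Path(path).write_text(json.dumps(doc, indent=1))
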