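"""Configuration files, trajectory tables, reports and run manifests.

No sequence/alignment format applies to this simulator, so interchange is
plain text: YAML configs (validated against an explicit schema, unknown keys
rejected), delimited trajectory tables (one row per time and cell, full
decimal precision so a write/read round trip is exact up to float
formatting), JSON reports, and a JSON run manifest written alongside every
output that records the tool version, a config hash, the seed and the
integrator statistics — enough to re-run a simulation exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .dynamics import ModelParams
from .kernels import (
    ActivationParams,
    KernelParams,
    UptakeDistanceParams,
    UptakeKernelParams,
    UptakeTimeParams,
)
from .simulate import InitSpec, SimulationConfig, Trajectory

__all__ = [
    "ConfigError",
    "TrajectoryParseError",
    "load_config",
    "dump_config",
    "config_to_dict",
    "write_trajectory",
    "read_trajectory",
    "write_report",
    "build_manifest",
    "write_manifest",
]

TRAJECTORY_COLUMNS = ["time", "cell_id", "x1", "x2", "v1", "v2", "p", "A"]


class ConfigError(ValueError):
    """A configuration file violates the schema."""


class TrajectoryParseError(ValueError):
    """A trajectory file cannot be parsed."""


# ---------------------------------------------------------------------------
# parameter (de)serialisation
# ---------------------------------------------------------------------------

_NESTED_MODEL_FIELDS = {
    "kernel1": KernelParams,
    "kernel2": KernelParams,
    "kernel3": KernelParams,
    "psiA": ActivationParams,
    "psiP": ActivationParams,
    "uptake_distance": UptakeDistanceParams,
    "uptake_kernel": UptakeKernelParams,
    "uptake_time": UptakeTimeParams,
}


def _to_plain(obj):
    if isinstance(obj, np.ndarray):
        return [float(v) for v in obj.ravel()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _build(cls, data: dict, section: str):
    if not isinstance(data, dict):
        raise ConfigError(f"section '{section}' must be a mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key '{sorted(unknown)[0]}' in section '{section}'")
    try:
        return cls(**data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value in section '{section}': {exc}") from exc


def model_params_from_dict(data: dict, defaults: ModelParams | None = None) -> ModelParams:
    """Build ModelParams from a plain mapping, filling gaps from ``defaults``."""
    base = _to_plain(defaults) if defaults is not None else {}
    known = {f.name for f in dataclasses.fields(ModelParams)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key '{sorted(unknown)[0]}' in section 'model'")
    merged = {**base, **{k: v for k, v in data.items() if k not in _NESTED_MODEL_FIELDS}}
    for name, cls in _NESTED_MODEL_FIELDS.items():
        sub = {**base.get(name, {}), **data.get(name, {})} if name in data else base.get(name, {})
        if sub:
            merged[name] = _build(cls, sub, f"model.{name}")
        else:
            merged.pop(name, None)
    try:
        return ModelParams(**merged)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value in section 'model': {exc}") from exc


def simulation_config_from_dict(
    data: dict, defaults: SimulationConfig | None = None
) -> SimulationConfig:
    base = _to_plain(defaults) if defaults is not None else {}
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key '{sorted(unknown)[0]}' in section 'simulation'")
    merged = {**base, **{k: v for k, v in data.items() if k != "init"}}
    init = {**base.get("init", {}), **data.get("init", {})}
    if init:
        merged["init"] = _build(InitSpec, init, "simulation.init")
    else:
        merged.pop("init", None)
    try:
        return SimulationConfig(**merged)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value in section 'simulation': {exc}") from exc


def config_to_dict(
    config: SimulationConfig, params: ModelParams, variant: str = "uncoupled"
) -> dict:
    return {
        "variant": variant,
        "simulation": _to_plain(config),
        "model": _to_plain(params),
    }


def load_config(path) -> tuple[SimulationConfig, ModelParams, str]:
    """Load and validate a YAML config; absent keys fall back to fig-defaults.

    The defaults are the velocity-consensus fixture; an empty file therefore
    yields exactly that scenario.
    """
    from .experiments import convergence_defaults

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - {"variant", "simulation", "model"}
    if unknown:
        raise ConfigError(f"unknown top-level key '{sorted(unknown)[0]}'")
    variant = raw.get("variant", "uncoupled")
    if variant not in ("uncoupled", "coupled"):
        raise ConfigError(f"variant must be 'uncoupled' or 'coupled', got {variant!r}")
    default_params, default_config = convergence_defaults()
    params = model_params_from_dict(raw.get("model", {}) or {}, defaults=default_params)
    config = simulation_config_from_dict(raw.get("simulation", {}) or {}, defaults=default_config)
    return config, params, variant


def dump_config(
    config: SimulationConfig, params: ModelParams, variant: str, path
) -> None:
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(config, params, variant), sort_keys=False)
    )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path) -> None:
    """Write a (time, cell) long-format CSV with full decimal precision."""
    rows = {
        "time": np.repeat(traj.times, traj.n_cells),
        "cell_id": np.tile(np.arange(traj.n_cells), len(traj.times)),
        "x1": traj.block("x")[:, :, 0].ravel(),
        "x2": traj.block("x")[:, :, 1].ravel(),
        "v1": traj.block("v")[:, :, 0].ravel(),
        "v2": traj.block("v")[:, :, 1].ravel(),
        "p": traj.block("p").ravel(),
        "A": traj.block("A").ravel(),
    }
    # %.17g guarantees an exact float round trip
    pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_trajectory(path) -> Trajectory:
    """Read a trajectory CSV back; inverse of :func:`write_trajectory`."""
    from .dynamics import PopulationState

    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise TrajectoryParseError(f"{path}: {exc}") from exc
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryParseError(f"{path}: missing column '{missing[0]}' (line 1)")
    bad = df[TRAJECTORY_COLUMNS[2:] + ["time"]].isna()
    if bad.to_numpy().any():
        row = int(np.argmax(bad.any(axis=1).to_numpy()))
        raise TrajectoryParseError(f"{path}: unparseable value near line {row + 2}")
    times = np.unique(df["time"].to_numpy())
    states = []
    for t in times:
        sub = df[df["time"] == t].sort_values("cell_id")
        states.append(
            PopulationState(
                x=sub[["x1", "x2"]].to_numpy(),
                v=sub[["v1", "v2"]].to_numpy(),
                p=sub["p"].to_numpy(),
                A=sub["A"].to_numpy(),
            )
        )
    return Trajectory(times=times, states=states)


# ---------------------------------------------------------------------------
# reports and manifests
# ---------------------------------------------------------------------------

def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def config_hash(config: SimulationConfig, params: ModelParams, variant: str) -> str:
    payload = json.dumps(config_to_dict(config, params, variant), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_manifest(traj: Trajectory) -> dict:
    """Self-describing record of a run: version, config hash, seed, stats."""
    cfg = traj.config
    return {
        "tool": "qsflock",
        "version": _version,
        "variant": traj.variant,
        "seed": cfg.seed if cfg else None,
        "config_hash": (
            config_hash(cfg, traj.params, traj.variant) if cfg and traj.params else None
        ),
        "config": config_to_dict(cfg, traj.params, traj.variant) if cfg and traj.params else None,
        "integrator": dict(traj.stats),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }


def write_manifest(traj: Trajectory, path) -> None:
    write_report(build_manifest(traj), path)
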