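"""Run configuration, result serialization and provenance.

Scalars and configs go to JSON, beat traces to CSV with a JSON sidecar.
Every result document embeds a provenance block (package version, config,
seed, solver settings) sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ord import CellType, Scaling, PacingConfig
from .trace import BeatTrace


def _version() -> str:
    try:
        return metadata.version("transmural")
    except metadata.PackageNotFoundError:
        return "unknown"


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

_CONFIG_DEFAULTS = {
    "cell": "EPI",
    "bcl_ms": 1000.0,
    "scaling": {},              # e.g. {"ikr": 0.75}
    "mode": "converged",
    "dt": 0.005,
    "dt_coarse": 0.05,
    "dt_output": 0.1,
    "stim_amplitude": None,
    "stim_duration": 0.5,
    "blockers_only": False,
    "seed": 0,
}


def validate_config(cfg: dict) -> dict:
    """Fill defaults and validate; errors name the offending key."""
    out = dict(_CONFIG_DEFAULTS)
    unknown = set(cfg) - set(out)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    out.update(cfg)
    CellType.parse(out["cell"])
    if not (400.0 <= float(out["bcl_ms"]) <= 3000.0):
        raise ValueError(f"bcl_ms={out['bcl_ms']} outside protocol range [400, 3000]")
    try:
        Scaling.from_dict(out["scaling"]).validate(
            blockers_only=bool(out["blockers_only"]))
    except ValueError as e:
        raise ValueError(f"scaling: {e}") from None
    if out["mode"] not in ("full", "converged", "fixed"):
        raise ValueError(f"mode={out['mode']!r} not one of full/converged/fixed")
    return out


def load_config(path) -> dict:
    """Load and validate a YAML or JSON run configuration."""
    p = Path(path)
    text = p.read_text()
    cfg = yaml.safe_load(text) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {p} must be a mapping")
    return validate_config(cfg)


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(validate_config(cfg), sort_keys=True))


def scaling_from_config(cfg: dict) -> Scaling:
    return Scaling.from_dict(cfg["scaling"])


def pacing_from_config(cfg: dict) -> PacingConfig:
    return PacingConfig(
        bcl=float(cfg["bcl_ms"]), mode=cfg["mode"], dt=float(cfg["dt"]),
        dt_coarse=float(cfg["dt_coarse"]), dt_output=float(cfg["dt_output"]),
        stim_amplitude=cfg["stim_amplitude"],
        stim_duration=float(cfg["stim_duration"]))


# --------------------------------------------------------------------------
# results
# --------------------------------------------------------------------------


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return {"__float__": repr(obj)}
    return obj


def provenance(config: dict | None = None, seed: int | None = None,
               solver: dict | None = None) -> dict:
    return {"package": "transmural", "version": _version(),
            "config": _jsonable(config or {}), "seed": seed,
            "solver": _jsonable(solver or {})}


def write_results(result, path, config: dict | None = None,
                  seed: int | None = None, solver: dict | None = None) -> None:
    """Serialize a result (dataclass or dict) to JSON with provenance."""
    doc = {"result": _jsonable(result),
           "provenance": provenance(config, seed, solver)}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_results(path) -> dict:
    return json.loads(Path(path).read_text())


def write_beat_csv(trace: BeatTrace, path) -> None:
    """Beat trace to CSV plus a ``<path>.json`` sidecar with metadata."""
    p = Path(path)
    trace.to_frame().to_csv(p, index=False, float_format="%.6g")
    sidecar = {"bcl_ms": trace.bcl, "meta": _jsonable(trace.meta),
               "provenance": provenance()}
    p.with_suffix(p.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n")


def read_beat_csv(path) -> BeatTrace:
    p = Path(path)
    df = pd.read_csv(p)
    bcl, meta = float("nan"), {}
    side = p.with_suffix(p.suffix + ".json")
    if side.exists():
        doc = json.loads(side.read_text())
        bcl = doc.get("bcl_ms", float("nan"))
        meta = doc.get("meta", {})
    return BeatTrace.from_frame(df, bcl=bcl, meta=meta)
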