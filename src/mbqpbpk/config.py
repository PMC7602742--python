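"""Configuration and dataset I/O.

Configs are YAML (or JSON) with optional blocks ``physiology``, ``compound``,
``kp``, ``clearances``, ``tumor``, ``tgi``, ``regimen`` and ``fit``; builders
turn validated blocks into model objects, filling anything omitted from the
MBQ-167 presets.  Datasets and results travel as tidy CSV with explicit unit
columns; internal units are fixed (ng, mL, h for PK; g, day for TGI) and
conversions happen only at this boundary.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import presets
from .compound import CompoundParams, assemble_final_kpset, predict_kp_method2
from .pbpk import Clearances, PBPKModel, build_pbpk_model, SimulationResult
from .physiology import build_mouse_physiology
from .regimen import RegimenSpec
from .tgi import TGIParams
from .tumor import TumorDispositionParams, attach_tumor

__all__ = [
    "load_config",
    "model_from_config",
    "tgi_from_config",
    "regimen_from_config",
    "read_dataset",
    "write_dataset",
    "write_simulation_result",
    "run_log_entry",
]

KNOWN_BLOCKS = {
    "physiology", "compound", "kp", "clearances", "tumor", "tgi", "regimen",
    "fit", "seed", "study",
}
KNOWN_UNITS = {"ng/mL", "mL", "g", "h", "day", ""}


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML/JSON config; unknown top-level keys reject."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    unknown = set(cfg) - KNOWN_BLOCKS
    if unknown:
        raise ValueError(f"unknown config block(s): {sorted(unknown)}")
    return cfg


def require_block(cfg: dict, name: str) -> dict:
    if name not in cfg:
        raise ValueError(f"config is missing the required {name!r} block")
    return cfg[name]


def _build_dataclass(cls, block: dict, what: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - names
    if unknown:
        raise ValueError(f"unknown key(s) in {what!r} block: {sorted(unknown)}")
    return cls(**block)


def model_from_config(cfg: dict) -> PBPKModel:
    """Build a (possibly tumor-bearing) PBPK model from a config mapping.

    Missing blocks fall back to the calibrated MBQ-167 reference
    parameterization.
    """
    phys_block = dict(cfg.get("physiology", {}))
    body_weight = float(phys_block.pop("body_weight", 20.0))
    phys = build_mouse_physiology(body_weight, overrides=phys_block or None)

    if "compound" in cfg or "clearances" in cfg or "kp" in cfg:
        comp_block = dict(cfg.get("compound", {}))
        compound = _build_dataclass(CompoundParams, comp_block, "compound") \
            if comp_block else presets.mbq167_compound()
        cl_block = dict(cfg.get("clearances", {}))
        clearances = _build_dataclass(Clearances, cl_block, "clearances") \
            if cl_block else Clearances(renal_cl=phys.gfr)
        kp_block = dict(cfg.get("kp", {}))
        overrides = kp_block.get("overrides", presets.KP_OVERRIDES)
        scalar = float(kp_block.get("scalar", presets.KP_SCALAR))
        kpset = assemble_final_kpset(predict_kp_method2(compound), overrides, scalar)
        model = build_pbpk_model(phys, compound, kpset, clearances)
    else:
        model = presets.build_reference_model(body_weight=body_weight)

    if "tumor" in cfg:
        tumor = _build_dataclass(TumorDispositionParams, dict(cfg["tumor"]), "tumor")
        model = attach_tumor(model, tumor)
    return model


def tgi_from_config(cfg: dict) -> TGIParams:
    block = require_block(cfg, "tgi")
    if isinstance(block, str):
        presets_map = {"her2": presets.tgi_her2, "tnbc": presets.tgi_tnbc}
        if block not in presets_map:
            raise ValueError(f"unknown tgi preset {block!r}")
        return presets_map[block]()
    return _build_dataclass(TGIParams, dict(block), "tgi")


def regimen_from_config(cfg: dict) -> RegimenSpec:
    block = require_block(cfg, "regimen")
    return _build_dataclass(RegimenSpec, dict(block), "regimen")


DATASET_COLUMNS = ["study", "subject_id", "group", "output", "time",
                   "time_unit", "value", "value_unit", "truth"]


def write_dataset(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_dataset(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"time", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"dataset is missing column(s): {sorted(missing)}")
    for col in ("time_unit", "value_unit"):
        if col in df.columns:
            bad = set(df[col].astype(str).unique()) - KNOWN_UNITS
            if bad:
                raise ValueError(f"unknown unit string(s) in {col}: {sorted(bad)}")
    return df


def write_simulation_result(result: SimulationResult, path: str | Path) -> None:
    write_dataset(result.to_frame(), path)


def run_log_entry(cfg: dict, seed: int | None) -> str:
    """One ISO-8601-stamped log line recording config hash, seed and version."""
    from . import __version__

    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
    return f"{stamp} mbqpbpk={__version__} config_sha256={digest} seed={seed}"
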