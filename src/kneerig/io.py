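"""Recording file format and run configuration.

Recordings are stored as a long-format CSV, one row per sample, with a
versioned ``#``-comment header line.  Numeric fields are written with 17
significant digits so a write/read cycle is bit-exact for doubles.
Poses are expressed relative to each specimen's zero position (tibial
position at 30 deg flexion with all loads nulled), which is the
convention the analysis assumes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pipeline import TrialRecording
from .synthetic_rig import RigConfig, TissueModel

__all__ = [
    "SCHEMA_VERSION",
    "SchemaError",
    "ConfigError",
    "AnalysisOptions",
    "RunConfig",
    "read_recordings",
    "write_recordings",
    "load_config",
]

SCHEMA_VERSION = "kneerig-recordings v1"

_META_COLS = ["specimen", "flexion_angle", "state", "cycle", "phase",
              "target_load", "control_fluctuation", "time"]
_ROT_COLS = [f"r{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)]  # row-major
_TRANS_COLS = ["tx", "ty", "tz"]
_WRENCH_COLS = ["fx", "fy", "fz", "mx", "my", "mz"]
COLUMNS = _META_COLS + _ROT_COLS + _TRANS_COLS + _WRENCH_COLS


class SchemaError(ValueError):
    """Recording file violates the CSV schema."""


class ConfigError(ValueError):
    """Run configuration is invalid."""


def write_recordings(recordings, path) -> None:
    """Write recordings to the long-format CSV schema (lossless)."""
    frames = []
    for rec in recordings:
        n = rec.n_samples
        df = pd.DataFrame({
            "specimen": rec.specimen,
            "flexion_angle": rec.flexion_angle,
            "state": rec.state,
            "cycle": rec.cycle,
            "phase": rec.phase,
            "target_load": rec.target_load,
            "control_fluctuation": rec.control_fluctuation,
            "time": rec.times,
        })
        rot = rec.rotations.reshape(n, 9)
        for k, col in enumerate(_ROT_COLS):
            df[col] = rot[:, k]
        for k, col in enumerate(_TRANS_COLS):
            df[col] = rec.translations[:, k]
        for k, col in enumerate(_WRENCH_COLS):
            df[col] = rec.wrenches[:, k]
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# {SCHEMA_VERSION}\n")
        out.to_csv(fh, index=False, float_format="%.17g")


def read_recordings(path) -> list[TrialRecording]:
    """Read a recording CSV, validating the schema.

    Raises :class:`SchemaError` naming the missing column or the
    offending data row (1-based, excluding header/comment lines).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty recording file") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")
    numeric = [c for c in COLUMNS if c not in ("specimen", "state", "phase")]
    for c in numeric:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    bad = df[numeric].isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise SchemaError(f"{path}: non-numeric or missing value in data row {row}")

    recordings: list[TrialRecording] = []
    keys = ["specimen", "flexion_angle", "state", "cycle", "phase"]
    for key, g in df.groupby(keys, sort=False):
        specimen, angle, state, cycle, phase = key
        try:
            recordings.append(TrialRecording(
                specimen=str(specimen),
                flexion_angle=float(angle),
                state=str(state),
                cycle=int(cycle),
                phase=str(phase),
                times=g["time"].to_numpy(),
                rotations=g[_ROT_COLS].to_numpy().reshape(-1, 3, 3),
                translations=g[_TRANS_COLS].to_numpy(),
                wrenches=g[_WRENCH_COLS].to_numpy(),
                target_load=float(g["target_load"].iloc[0]),
                control_fluctuation=float(g["control_fluctuation"].iloc[0]),
            ))
        except ValueError as exc:
            row = int(g.index[0]) + 1
            raise SchemaError(
                f"{path}: invalid trial starting at data row {row}: {exc}"
            ) from exc
    return recordings


@dataclass(frozen=True)
class AnalysisOptions:
    """Statistical-analysis options for the default report."""

    alpha: float = 0.05
    sphericity_correction: bool = False
    output_dir: str = "kneerig-out"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class RunConfig:
    """One document holding rig, tissue and analysis configuration."""

    rig: RigConfig = field(default_factory=RigConfig)
    tissue: TissueModel = field(default_factory=TissueModel)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)


def _build(cls, section: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in '{name}' section: {sorted(unknown)}")
    coerced = dict(section)
    for f in dataclasses.fields(cls):
        if f.name in coerced and isinstance(coerced[f.name], list):
            coerced[f.name] = tuple(coerced[f.name])
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{name}' section: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load a YAML or JSON run configuration; unknown keys are rejected."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"{path}: cannot parse configuration: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(doc) - {"rig", "tissue", "analysis"}
    if unknown:
        raise ConfigError(f"{path}: unknown top-level key(s): {sorted(unknown)}")
    return RunConfig(
        rig=_build(RigConfig, doc.get("rig", {}) or {}, "rig"),
        tissue=_build(TissueModel, doc.get("tissue", {}) or {}, "tissue"),
        analysis=_build(AnalysisOptions, doc.get("analysis", {}) or {}, "analysis"),
    )
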