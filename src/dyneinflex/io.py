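"""Table formats, configuration and reports.

Tables are UTF-8 tab-separated text with '.' decimals.  The particle table
carries one row per visible head/ring on a microtubule; the run table one
row per single-molecule interaction event.  Unknown columns are preserved
and row order is kept.  Reports are JSON; images are 32-bit float TIFF.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import MotorGeometry
from .lattice import LatticeParams
from .synthgen import GenConfig, MechanicalParams

__all__ = [
    "FormatError",
    "PARTICLE_COLUMNS",
    "RUN_COLUMNS",
    "read_particle_table",
    "write_particle_table",
    "read_run_table",
    "write_run_table",
    "write_report",
    "write_micrograph",
    "KineticsConfig",
    "ReportConfig",
    "PipelineConfig",
    "load_config",
    "save_config",
]


class FormatError(ValueError):
    """Raised for malformed input tables or configuration files."""


PARTICLE_COLUMNS = [
    "particle_id",
    "mt_id",
    "axial_x_nm",
    "ring_height_nm",
    "n_rings_visible",
    "pixel_sum",
    "class_label",
]
_PARTICLE_NUMERIC = [
    "particle_id",
    "mt_id",
    "axial_x_nm",
    "ring_height_nm",
    "n_rings_visible",
    "pixel_sum",
]

RUN_COLUMNS = ["molecule_id", "run_length_nm", "duration_s", "velocity_nm_per_s"]
_RUN_NUMERIC = RUN_COLUMNS[1:]


def _read_table(path: Path | str, mandatory: list[str], numeric: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in mandatory:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column '{col}'")
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            # +2: one for the header line, one for 1-based numbering
            line = int(bad.idxmax()) + 2
            raise FormatError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column "
                f"'{col}' at line {line}"
            )
        df[col] = converted
    return df


def read_particle_table(path: Path | str) -> pd.DataFrame:
    """Read a particle table (TSV), validating columns and numeric types."""
    df = _read_table(path, PARTICLE_COLUMNS, _PARTICLE_NUMERIC)
    for col in ("particle_id", "mt_id", "n_rings_visible"):
        df[col] = df[col].astype(int)
    return df


def write_particle_table(df: pd.DataFrame, path: Path | str) -> None:
    for col in PARTICLE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"particle table lacks column '{col}'")
    df.to_csv(path, sep="\t", index=False)


def read_run_table(path: Path | str) -> pd.DataFrame:
    """Read a single-molecule run table (TSV)."""
    df = _read_table(path, RUN_COLUMNS, _RUN_NUMERIC)
    ids = pd.to_numeric(df["molecule_id"], errors="coerce")
    if not ids.isna().any():
        df["molecule_id"] = ids.astype(int)
    return df


def write_run_table(df: pd.DataFrame, path: Path | str) -> None:
    for col in RUN_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"run table lacks column '{col}'")
    df.to_csv(path, sep="\t", index=False)


class _ReportEncoder(json.JSONEncoder):
    def default(self, o: Any) -> Any:
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)

    # JSON object keys must be strings; numeric keys (separations) are
    # stringified by json automatically only for int -- coerce here.
    def iterencode(self, o: Any, _one_shot: bool = False):
        return super().iterencode(_stringify_keys(o), _one_shot)


def _stringify_keys(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _stringify_keys(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_stringify_keys(v) for v in obj]
    return obj


def write_report(report: dict, path: Path | str) -> None:
    """Write a JSON report with stable key order."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, cls=_ReportEncoder, indent=2, sort_keys=True)
        fh.write("\n")


def write_micrograph(image: np.ndarray, path: Path | str) -> None:
    """Write a rendered image as 32-bit float TIFF."""
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


@dataclasses.dataclass
class KineticsConfig:
    """Settings for the synthetic motility stage."""

    duty_ratio: float = 0.902
    step_nm: float = 8.3
    n_runs: int = 2000
    velocity_mean: float = 150.0  # nm/s
    velocity_sd: float = 30.0
    step_sizes: tuple[float, ...] = (4.15, 8.3, 16.6)
    criterion: str = "median"


@dataclasses.dataclass
class ReportConfig:
    """Analysis options shared across pipeline stages."""

    mode: str = "as_published"
    window: int = 100
    exclusion_nm: float = 40.0
    pair_window_nm: float = 40.0


@dataclasses.dataclass
class PipelineConfig:
    """Everything the pipeline needs, serializable to one YAML file."""

    lattice: LatticeParams = dataclasses.field(default_factory=LatticeParams)
    motor: MotorGeometry = dataclasses.field(default_factory=MotorGeometry)
    mechanical: MechanicalParams = dataclasses.field(default_factory=MechanicalParams)
    generation: GenConfig = dataclasses.field(default_factory=GenConfig)
    kinetics: KineticsConfig = dataclasses.field(default_factory=KineticsConfig)
    report: ReportConfig = dataclasses.field(default_factory=ReportConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # YAML mapping keys must round-trip; separation weights use floats
        d["generation"]["separation_weights"] = {
            float(k): float(v)
            for k, v in self.generation.separation_weights.items()
        }
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def build(klass, key):
            sub = dict(data.get(key) or {})
            try:
                return klass(**sub)
            except TypeError as exc:
                raise FormatError(f"bad '{key}' section: {exc}") from exc

        gen_section = dict(data.get("generation") or {})
        if "separation_weights" in gen_section:
            gen_section["separation_weights"] = {
                float(k): float(v)
                for k, v in gen_section["separation_weights"].items()
            }
        kin_section = dict(data.get("kinetics") or {})
        if "step_sizes" in kin_section:
            kin_section["step_sizes"] = tuple(kin_section["step_sizes"])
        try:
            generation = GenConfig(**gen_section) if gen_section else GenConfig()
            kinetics = KineticsConfig(**kin_section) if kin_section else KineticsConfig()
        except TypeError as exc:
            raise FormatError(str(exc)) from exc
        return cls(
            lattice=build(LatticeParams, "lattice"),
            motor=build(MotorGeometry, "motor"),
            mechanical=build(MechanicalParams, "mechanical"),
            generation=generation,
            kinetics=kinetics,
            report=build(ReportConfig, "report"),
            seed=int(data.get("seed", 0)),
        )


def load_config(path: Path | str) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: top level must be a mapping")
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: Path | str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
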