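"""Peak-table I/O and run configuration.

Peak tables are comma-separated UTF-8 text with a mandatory header and a
decimal point (never a decimal comma, stated explicitly because chromatography
labs in decimal-comma locales routinely export the other way). One row per
detected peak per injection.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .simulate import PEAK_COLUMNS, SAMPLE_TYPES

logger = logging.getLogger("terpfet")

_NUMERIC = ["rt_min", "area_target", "area_q1", "area_q2", "sample_weight_mg",
            "thermostat_temp_c", "thermostat_time_min", "injection_index"]


class PeakTableError(ValueError):
    pass


def read_peak_table(path) -> pd.DataFrame:
    """Read and validate a peak-table CSV.

    Malformed rows are reported with their 1-based line number (header is
    line 1). A header-only file yields an empty table with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise PeakTableError(f"{path}: missing required column(s): {missing}")
    if df.empty:
        logger.warning("%s: peak table contains a header but no records", path)
        return df[PEAK_COLUMNS]

    problems = []
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        for i in bad:
            problems.append(f"line {i + 2}: non-numeric {col}={df.loc[i, col]!r}")
        df[col] = coerced
    for col in ("area_target", "area_q1", "area_q2"):
        for i in df.index[df[col] < 0]:
            problems.append(f"line {i + 2}: negative {col}={df.loc[i, col]}")
    for i in df.index[df["injection_index"] < 1]:
        problems.append(f"line {i + 2}: injection_index < 1")
    for i in df.index[~df["sample_type"].isin(SAMPLE_TYPES)]:
        problems.append(f"line {i + 2}: unknown sample_type={df.loc[i, 'sample_type']!r}")
    if problems:
        raise PeakTableError(f"{path}: " + "; ".join(problems[:20]))
    df["injection_index"] = df["injection_index"].astype(int)
    return df[PEAK_COLUMNS]


def write_peak_table(df: pd.DataFrame, path) -> None:
    df[PEAK_COLUMNS].to_csv(path, index=False)


@dataclass
class RunConfig:
    """Serialisable configuration for a pipeline run."""

    output_dir: str = "terpfet_out"
    peak_table: str | None = None     # input CSV; None = simulate
    stages: tuple[str, ...] = ("simulate", "verify-fet", "calibrate", "quantify", "profile")
    seed: int = 0
    noise_rsd: float = 0.05
    extraction_fraction: float = 0.30
    adsorption_excess: float = 0.0
    calibration_replicates: int = 3
    qualifier_tolerance: float = 0.30
    rt_window_min: float = 0.15
    plateau_tolerance: float = 0.30
    mhe_deviation_limit: float = 30.0
    din_alpha: float = 0.01
    din_k: float = 3.0
    din_m: int = 1
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    @property
    def config_hash(self) -> str:
        data = asdict(self)
        data["stages"] = list(self.stages)
        blob = json.dumps(data, sort_keys=True).encode("utf-8")
        return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(config: RunConfig, path) -> None:
    """Stamp an output directory with the config hash and seed."""
    Path(path).write_text(json.dumps(
        {"config_hash": config.config_hash, "seed": config.seed}, indent=2),
        encoding="utf-8")
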