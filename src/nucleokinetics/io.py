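"""Table I/O, run configuration and manifests for the CLI pipeline.

All tables are UTF-8 CSV with a header row and "." decimal separator.
Units are carried in the run manifest (a YAML sidecar written next to the
data), not in column names. Every stochastic run records its seed in the
manifest so any output is reproducible byte-for-byte from manifest + seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

log = logging.getLogger("nucleokinetics")

LANES_COLUMNS = ["lane", "condition", "replicate", "nuc_intensity", "free_intensity"]
BLOTS_COLUMNS = ["lane", "target", "intensity"]
MELT_COLUMNS = ["temperature_C", "fluorescence", "sample"]

#: Unit declarations recorded with every manifest.
DEFAULT_UNITS = {
    "Q_ug_ml": "ug/mL",
    "time_h": "h",
    "nuc_intensity": "arbitrary fluorescence units",
    "free_intensity": "arbitrary fluorescence units",
    "intensity": "arbitrary fluorescence units",
    "temperature_C": "degC",
}


class SchemaError(ValueError):
    """A table does not match its declared column schema."""


@dataclass
class RunConfig:
    """Parameters of one CLI run (subset used varies by subcommand)."""

    seed: int = 0
    mode: str = "linear"            # linear | explicit | ode
    noise_cv: float = 0.10
    replicates: int = 5
    slope: float | None = None      # composite slope for synth, per ug/mL
    ratio: float | None = None      # injected kbar_A/kbar_Z for synth
    total_mass: float = 3.0         # competition design selector, ug
    units: dict = field(default_factory=lambda: dict(DEFAULT_UNITS))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = cls.__dataclass_fields__
        bad = set(raw) - set(known)
        if bad:
            raise SchemaError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


def _validate(df: pd.DataFrame, columns: list[str], what: str, path) -> pd.DataFrame:
    if df.empty and df.columns.size == 0:
        raise SchemaError(f"{what} file {path} is empty")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file {path} missing columns {missing}; has {list(df.columns)}")
    for col in columns:
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0])
            raise SchemaError(f"{what} file {path}: missing value in column {col!r}, row {row}")
    return df


def read_lanes(path) -> pd.DataFrame:
    return _validate(pd.read_csv(path), LANES_COLUMNS, "lanes", path)


def read_blots(path) -> pd.DataFrame:
    return _validate(pd.read_csv(path), BLOTS_COLUMNS, "blots", path)


def read_melt(path) -> pd.DataFrame:
    return _validate(pd.read_csv(path), MELT_COLUMNS, "melt", path)


def write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    log.info("wrote %s (%d rows)", path, len(df))


def write_manifest(path, payload: dict) -> None:
    """Record seed, parameters and units of a run as YAML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    log.info("wrote manifest %s", path)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
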