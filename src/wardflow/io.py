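"""Delimited-text file formats and run configuration.

All tables are comma-delimited with a mandatory header row; timestamps are
ISO-8601 local time at seconds precision, dates ISO-8601, booleans
``true``/``false``, missing values empty.  Readers validate the schema:
missing columns always abort; malformed rows abort in ``strict`` mode
(naming the rows) or are dropped with a log line in ``skip`` mode; unknown
columns are rejected in strict mode and warned about otherwise.
Write-then-read is an identity on every table.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, SchemaError
from .inference import FdrParams
from .resources import ResourceParams
from .sessionize import SessionizeParams
from .simulate import StageWindow

logger = logging.getLogger(__name__)

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%S"

_TS, _DATE, _BOOL, _STR, _INT, _FLOAT = "ts", "date", "bool", "str", "int", "float"

SCHEMAS = {
    "events": {
        "nurse_id": _STR, "role": _STR, "unit_id": _STR, "room_id": _STR,
        "t_start": _TS, "t_end": _TS,
    },
    "census": {
        "unit_id": _STR, "room_id": _STR, "census_date": _DATE,
        "occupied": _BOOL, "covid_status": _STR,
    },
    "calls": {
        "unit_id": _STR, "t_start": _TS, "t_end": _TS, "n_participants": _INT,
    },
    "encounters": {
        "nurse_id": _STR, "unit_id": _STR, "room_id": _STR,
        "t_start": _TS, "t_end": _TS, "duration_s": _FLOAT, "n_fragments": _INT,
    },
    "daily": {
        "unit_id": _STR, "arm": _STR, "shift_date": _DATE, "shift": _STR,
        "n_patients": _INT, "n_encounters": _INT,
        "encounters_per_patient": _FLOAT, "median_encounter_min": _FLOAT,
        "median_total_min_per_patient": _FLOAT,
    },
    "linked": {
        "nurse_id": _STR, "unit_id": _STR, "room_id": _STR,
        "t_start": _TS, "t_end": _TS, "duration_s": _FLOAT, "n_fragments": _INT,
        "shift_date": _DATE, "shift": _STR, "occupied": _BOOL,
        "covid_status": _STR, "flag": _STR,
    },
}


def _parse_column(s: pd.Series, kind: str) -> tuple[pd.Series, pd.Series]:
    """Parse one column; returns (parsed, bad-row mask)."""
    if kind == _TS:
        out = pd.to_datetime(s, errors="coerce")
        return out, out.isna() & s.notna() & (s.astype(str).str.len() > 0)
    if kind == _DATE:
        out = pd.to_datetime(s, errors="coerce")
        return out.dt.date, out.isna() & s.notna()
    if kind == _BOOL:
        if pd.api.types.is_bool_dtype(s):
            return s, pd.Series(False, index=s.index)
        low = s.astype(str).str.lower()
        bad = ~low.isin(["true", "false"])
        return low == "true", bad
    if kind == _INT:
        out = pd.to_numeric(s, errors="coerce")
        bad = out.isna()
        return out.fillna(0).astype(int), bad
    if kind == _FLOAT:
        out = pd.to_numeric(s, errors="coerce")
        return out, out.isna() & s.notna() & (s.astype(str).str.len() > 0)
    return s.astype(str), pd.Series(False, index=s.index)


def read_table(path, schema_name: str, on_error: str = "strict") -> pd.DataFrame:
    """Read and schema-validate one of the package's delimited formats."""
    if on_error not in ("strict", "skip"):
        raise ValueError("on_error must be 'strict' or 'skip'")
    schema = SCHEMAS[schema_name]
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except OSError as exc:
        raise SchemaError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in schema if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    unknown = [c for c in raw.columns if c not in schema]
    if unknown:
        if on_error == "strict":
            raise SchemaError(f"{path}: unknown column(s) {unknown}")
        logger.warning("%s: ignoring unknown column(s) %s", path, unknown)

    out = pd.DataFrame(index=raw.index)
    bad = pd.Series(False, index=raw.index)
    for col, kind in schema.items():
        parsed, b = _parse_column(raw[col].replace("", np.nan), kind)
        out[col] = parsed
        bad |= b
    # interval sanity where both endpoints exist
    if "t_start" in schema and "t_end" in schema:
        bad |= out["t_end"] < out["t_start"]
    if bad.any():
        rows = out.index[bad].tolist()
        if on_error == "strict":
            raise SchemaError(
                f"{path}: {len(rows)} malformed row(s) at index {rows[:20]}",
                rows=rows,
            )
        logger.warning("%s: dropping %d malformed row(s)", path, len(rows))
        out = out[~bad]
    return out.reset_index(drop=True)


def write_table(df: pd.DataFrame, path, schema_name: str) -> None:
    """Write one of the package's delimited formats (lossless round-trip)."""
    schema = SCHEMAS[schema_name]
    out = pd.DataFrame(index=df.index)
    for col, kind in schema.items():
        if col not in df.columns:
            raise SchemaError(f"cannot write {schema_name}: missing column {col!r}")
        s = df[col]
        if kind == _TS:
            out[col] = pd.to_datetime(s).dt.strftime(TIMESTAMP_FORMAT)
        elif kind == _DATE:
            out[col] = s.map(lambda d: d.isoformat() if d is not None else "")
        elif kind == _BOOL:
            out[col] = s.map(lambda v: "true" if bool(v) else "false")
        else:
            out[col] = s
    out.to_csv(path, index=False)


def read_events(path, on_error="strict"):
    return read_table(path, "events", on_error)


def read_census(path, on_error="strict"):
    return read_table(path, "census", on_error)


def read_calls(path, on_error="strict"):
    return read_table(path, "calls", on_error)


def read_encounters(path, on_error="strict"):
    return read_table(path, "encounters", on_error)


def read_daily(path, on_error="strict"):
    return read_table(path, "daily", on_error)


def read_linked(path, on_error="strict"):
    return read_table(path, "linked", on_error)


def write_events(df, path):
    write_table(df, path, "events")


def write_census(df, path):
    write_table(df, path, "census")


def write_calls(df, path):
    write_table(df, path, "calls")


def write_encounters(df, path):
    write_table(df, path, "encounters")


def write_daily(df, path):
    write_table(df, path, "daily")


def write_linked(df, path):
    write_table(df, path, "linked")


# -- run configuration ------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end pipeline settings; round-trips losslessly through YAML."""

    stages: tuple
    arm_of: dict
    sessionize: SessionizeParams = field(default_factory=SessionizeParams)
    pm_census: str = "next"
    baseline: str = "prepandemic"
    fdr: FdrParams = field(default_factory=FdrParams)
    fdr_family: str = "per_outcome"
    resources: ResourceParams = field(default_factory=ResourceParams)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "name": s.name,
                    "start_date": s.start_date.isoformat(),
                    "end_date": s.end_date.isoformat(),
                }
                for s in self.stages
            ],
            "arm_of": dict(self.arm_of),
            "sessionize": {
                "min_event_s": self.sessionize.min_event_s,
                "merge_gap_s": self.sessionize.merge_gap_s,
                "included_roles": sorted(self.sessionize.included_roles),
            },
            "pm_census": self.pm_census,
            "baseline": self.baseline,
            "fdr": {"q": self.fdr.q, "method": self.fdr.method},
            "fdr_family": self.fdr_family,
            "resources": dataclasses.asdict(self.resources),
            "seed": self.seed,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sess = d.get("sessionize", {})
        if "included_roles" in sess:
            sess = {**sess, "included_roles": frozenset(sess["included_roles"])}
        return cls(
            stages=tuple(
                StageWindow(s["name"], s["start_date"], s["end_date"])
                for s in d["stages"]
            ),
            arm_of=dict(d["arm_of"]),
            sessionize=SessionizeParams(**sess),
            pm_census=d.get("pm_census", "next"),
            baseline=d.get("baseline", "prepandemic"),
            fdr=FdrParams(**d.get("fdr", {})),
            fdr_family=d.get("fdr_family", "per_outcome"),
            resources=ResourceParams(**d.get("resources", {})),
            seed=int(d.get("seed", 0)),
            log_level=d.get("log_level", "INFO"),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: not a mapping")
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stages_from_yaml(path):
    """Load a stage calendar from YAML (list of name/start_date/end_date)."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    items = d["stages"] if isinstance(d, dict) and "stages" in d else d
    return tuple(
        StageWindow(s["name"], s["start_date"], s["end_date"]) for s in items
    )
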