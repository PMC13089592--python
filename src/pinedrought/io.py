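"""Schema-validated CSV readers/writers for the pipeline's tabular formats.

All files are UTF-8, comma-separated, with a mandatory header row,
ISO-8601 timestamps and "." decimals.  Every file written by the pipeline
gets a JSON sidecar (``<name>.meta.json``) recording the configuration hash
and master seed, so any output can be traced to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd


class SchemaError(ValueError):
    pass


#: column -> dtype kind ("datetime", "float", "int", "str"); "key" columns
#: must be jointly unique; "sort_within" demands strictly increasing
#: timestamps per group.
SCHEMAS: dict[str, dict] = {
    "env": {
        "columns": {
            "timestamp": "datetime",
            "compartment": "str",
            "doy": "int",
            "T_air": "float",
            "RH": "float",
            "VPD": "float",
            "PAR": "float",
            "SWC": "float",
        },
        "key": ["compartment", "timestamp"],
        "sort_within": "compartment",
    },
    "needles": {
        "columns": {
            "tree_id": "str",
            "treatment": "str",
            "doy": "int",
            "needle_id": "int",
            "length_mm": "float",
        },
        "key": ["tree_id", "needle_id", "doy"],
    },
    "dendro": {
        "columns": {
            "tree_id": "str",
            "treatment": "str",
            "timestamp": "datetime",
            "diameter_mm": "float",
            "initial_diameter_mm": "float",
        },
        "key": ["tree_id", "timestamp"],
        "sort_within": "tree_id",
    },
    "sapflow": {
        "columns": {
            "tree_id": "str",
            "treatment": "str",
            "timestamp": "datetime",
            "signal_w": "float",
        },
        "key": ["tree_id", "timestamp"],
        "sort_within": "tree_id",
    },
    "biomass": {
        "columns": {
            "tree_id": "str",
            "treatment": "str",
            "bud_g": "float",
            "needles_current_g": "float",
            "needles_old_g": "float",
            "wood_g": "float",
            "root_g": "float",
        },
        "key": ["tree_id"],
    },
}


def validate_frame(df: pd.DataFrame, schema_name: str) -> pd.DataFrame:
    """Validate (and coerce) a frame against a named schema."""
    if schema_name not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_name!r}; known: {sorted(SCHEMAS)}")
    spec = SCHEMAS[schema_name]
    missing = [c for c in spec["columns"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema_name}: missing columns {missing}")
    out = df.copy()
    bad = []
    for col, kind in spec["columns"].items():
        try:
            if kind == "datetime":
                out[col] = pd.to_datetime(out[col])
            elif kind == "float":
                out[col] = pd.to_numeric(out[col], errors="raise").astype(float)
            elif kind == "int":
                out[col] = pd.to_numeric(out[col], errors="raise").astype(int)
            else:
                out[col] = out[col].astype(str)
        except (ValueError, TypeError):
            bad.append(col)
    if bad:
        raise SchemaError(f"{schema_name}: columns with unparseable values: {bad}")
    key = spec.get("key")
    if key:
        dup = out.duplicated(subset=key)
        if dup.any():
            rows = list(out.index[dup][:10])
            raise SchemaError(f"{schema_name}: duplicated key {key} at rows {rows}")
    group = spec.get("sort_within")
    if group and "timestamp" in out.columns:
        for g, sub in out.groupby(group):
            ts = pd.DatetimeIndex(sub["timestamp"])
            if not ts.is_monotonic_increasing:
                raise SchemaError(f"{schema_name}: timestamps not increasing within {group}={g!r}")
    return out


def validate_and_read(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read a CSV and validate it against the named schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return validate_frame(pd.read_csv(path), schema_name)


def config_hash(payload) -> str:
    """Stable short hash of a JSON-serialisable configuration payload."""
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def write_csv_with_meta(df: pd.DataFrame, path: str | Path, meta: dict) -> Path:
    """Write a CSV plus a ``.meta.json`` sidecar (config hash, seed, rows)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps({**meta, "rows": int(len(df))}, indent=1, default=str))
    return path
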