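"""Validated I/O: long-format measurement tables, diet signatures,
run configuration and reproducibility manifests.

The CSV dialect is pinned: comma separator, ``.`` decimal, UTF-8,
LF line endings, header row mandatory.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MEASUREMENT_COLUMNS",
    "SchemaError",
    "validate_measurements",
    "read_measurements",
    "write_table",
    "read_diet_signatures",
    "load_config",
    "validate_config",
    "write_manifest",
]

MEASUREMENT_COLUMNS = ("individual_id", "sex", "age", "diet", "tissue",
                       "isotope", "day", "delta_permil")
OPTIONAL_COLUMNS = ("c_n_ratio",)

_ALLOWED = {
    "sex": {"F", "M"},
    "age": {"adult", "yearling"},
    "diet": {"mix", "terrestrial", "marine"},
    "isotope": {"d13C", "d15N"},
}


class SchemaError(ValueError):
    """A table does not conform to the long-format measurement schema."""


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format measurement table; returns it unchanged.

    Raises :class:`SchemaError` listing every offending column/row.
    """
    problems = []
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing required columns: {sorted(missing)}")
    unknown = set(df.columns) - set(MEASUREMENT_COLUMNS) - set(OPTIONAL_COLUMNS)
    if unknown:
        problems.append(f"unknown columns: {sorted(unknown)}")
    for col, allowed in _ALLOWED.items():
        bad = df.loc[~df[col].astype(str).isin(allowed)]
        if len(bad):
            problems.append(
                f"column {col!r}: invalid values {sorted(bad[col].astype(str).unique())} "
                f"in rows {bad.index.tolist()[:10]} (allowed: {sorted(allowed)})")
    day = pd.to_numeric(df["day"], errors="coerce")
    bad_day = df.index[day.isna() | (day < 0)].tolist()
    if bad_day:
        problems.append(f"column 'day': non-numeric or negative in rows {bad_day[:10]}")
    delta = pd.to_numeric(df["delta_permil"], errors="coerce")
    bad_delta = df.index[~np.isfinite(delta.to_numpy(float))].tolist()
    if bad_delta:
        problems.append(f"column 'delta_permil': non-finite in rows {bad_delta[:10]}")
    if "c_n_ratio" in df.columns:
        cn = pd.to_numeric(df["c_n_ratio"], errors="coerce")
        bad_cn = df.index[cn.notna() & (cn <= 0)].tolist()
        if bad_cn:
            problems.append(f"column 'c_n_ratio': non-positive in rows {bad_cn[:10]}")
    if problems:
        raise SchemaError("; ".join(problems))
    return df


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format measurement CSV."""
    df = pd.read_csv(path, encoding="utf-8")
    df = validate_measurements(df)
    df["day"] = df["day"].astype(float)
    df["delta_permil"] = df["delta_permil"].astype(float)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table in the pinned CSV dialect (atomically)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(df.to_csv(index=False, lineterminator="\n"), encoding="utf-8")
    tmp.replace(path)


def read_diet_signatures(path: str | Path) -> pd.DataFrame:
    """Read a diet-signature CSV (diet, isotope, delta_permil[, c_n_ratio])."""
    df = pd.read_csv(path, encoding="utf-8")
    required = {"diet", "isotope", "delta_permil"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"diet signature file missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["diet", "isotope"])
    if dup.any():
        raise SchemaError("duplicate diet/isotope signature rows: "
                          f"{df.loc[dup, ['diet', 'isotope']].to_dict('records')}")
    return df


# ---------------------------------------------------------------------------
# Run configuration and manifests
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError("config file must contain a key-value mapping")
    return cfg


def validate_config(cfg: Mapping, allowed: Mapping[str, type],
                    required: tuple[str, ...] = (),
                    stochastic: bool = False) -> dict:
    """Schema-check a command configuration.

    Unknown keys are rejected by name; ``seed`` is mandatory for any
    stochastic command.
    """
    unknown = set(cfg) - set(allowed)
    if unknown:
        raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
    for key in required:
        if key not in cfg:
            raise SchemaError(f"missing required config key: {key!r}")
    if stochastic and cfg.get("seed") is None:
        raise SchemaError("a seed is required for stochastic commands")
    out = {}
    for key, value in cfg.items():
        want = allowed[key]
        if want is float and isinstance(value, int):
            value = float(value)
        if not isinstance(value, want):
            raise SchemaError(
                f"config key {key!r} must be {getattr(want, '__name__', want)}, "
                f"got {type(value).__name__}")
        out[key] = value
    return out


def config_hash(cfg: Mapping) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()


def write_manifest(out_dir: str | Path, command: str, cfg: Mapping,
                   seed: int | None) -> Path:
    """Write a run manifest sufficient to reproduce the run.

    Deliberately timestamp-free so identical config + seed produce
    byte-identical output.
    """
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # The output location identifies where a run went, not what it was:
    # it is excluded so runs of one config are comparable across dirs.
    content_cfg = {k: v for k, v in cfg.items() if k != "out"}
    manifest = {
        "command": command,
        "seed": seed,
        "version": __version__,
        "config": content_cfg,
        "config_sha256": config_hash(content_cfg),
    }
    path = out_dir / "manifest.json"
    tmp = path.with_suffix(".tmp")
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n",
                   encoding="utf-8")
    tmp.replace(path)
    return path
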