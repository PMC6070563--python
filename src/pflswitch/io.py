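"""Parameter-file and run-manifest serialization.

Parameter files are schema-versioned JSON holding one ``parameters``
mapping plus optional metadata (mode, dose scale, notes); numeric tables
go to plain CSV (comma, '.' decimal, header, UTF-8).  Every pipeline
output directory carries a manifest with the full configuration, the seed
and a config hash, so any run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from .params import KineticParameters

SCHEMA_VERSION = 1

_META_KEYS = {"schema", "mode", "description", "dose_scale", "dox_level",
              "bistable_stimulus"}


class ParameterFileError(ValueError):
    pass


def read_params(path) -> KineticParameters:
    """Read a JSON parameter file; unknown keys and invariant violations
    are rejected with named errors."""
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ParameterFileError(f"{path}: not valid JSON ({e})") from e
    if not isinstance(data, dict) or "parameters" not in data:
        raise ParameterFileError(f"{path}: missing 'parameters' object")
    unknown = set(data) - _META_KEYS - {"parameters"}
    if unknown:
        raise ParameterFileError(f"{path}: unknown top-level keys {sorted(unknown)}")
    schema = data.get("schema", SCHEMA_VERSION)
    if schema != SCHEMA_VERSION:
        raise ParameterFileError(f"{path}: unsupported schema version {schema}")
    try:
        return KineticParameters.from_dict(data["parameters"])
    except Exception as e:
        raise ParameterFileError(f"{path}: {e}") from e


def write_params(path, params: KineticParameters, **meta) -> None:
    """Write a parameter file; ``read_params(write_params(...))`` is a
    lossless round trip."""
    unknown = set(meta) - _META_KEYS
    if unknown:
        raise ParameterFileError(f"unknown metadata keys {sorted(unknown)}")
    data = {"schema": SCHEMA_VERSION, **meta, "parameters": params.to_dict()}
    Path(path).write_text(json.dumps(data, indent=1) + "\n")


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(outdir, subcommand: str, config: dict, seed: int | None) -> Path:
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subcommand": subcommand,
        "config": config,
        "seed": seed,
        "config_hash": config_hash(config),
        "package_version": __version__,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str) + "\n")
    return path
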