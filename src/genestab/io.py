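"""Configuration and table I/O used by the command-line pipeline.

Configs are flat (one nesting level at most) YAML key-value files; CLI
flags override file values.  Every emitted table is comma-separated with
a header row, preceded by ``#``-prefixed metadata lines recording the
package version, the config hash and the seed, so a run can be traced
back to its exact inputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__

__all__ = [
    "read_config",
    "config_hash",
    "write_table",
    "read_table",
    "write_json",
    "model_params_from_config",
    "gompertz_params_from_config",
]

MODEL_KEYS = ("beta", "p", "G", "K", "c", "delta", "f_p", "f_g", "omega")


def read_config(path: str | Path, known_keys: set[str] | None = None) -> dict:
    """Load a flat YAML config; unknown keys are rejected when a schema is given."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    if known_keys is not None:
        unknown = set(cfg) - known_keys
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def config_hash(cfg: dict) -> str:
    """Short stable hash of a config dict (order-independent)."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _metadata_lines(meta: dict) -> str:
    lines = [f"# genestab {__version__}"]
    for k, v in meta.items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """CSV with '#' metadata comment lines above the header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_metadata_lines(meta or {}))
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(obj: dict, path: str | Path, meta: dict | None = None) -> None:
    payload = {"_meta": {"version": __version__, **(meta or {})}, **obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def model_params_from_config(cfg: dict):
    """Build :class:`~genestab.core.ModelParams` from flat config keys."""
    from .core import ModelParams

    kwargs = {k: float(cfg[k]) for k in MODEL_KEYS if k in cfg}
    if "coupling_includes_G" in cfg:
        kwargs["coupling_includes_G"] = bool(cfg["coupling_includes_G"])
    return ModelParams(**kwargs)


def gompertz_params_from_config(cfg: dict):
    """Build :class:`~genestab.demography.GompertzParams` from config keys."""
    from .demography import GompertzParams

    model = cfg.get("hazard_model", "gompertz")
    if model == "constant":
        return GompertzParams(M0=float(cfg["Mbar"]), model="constant")
    return GompertzParams(M0=float(cfg["M0"]), Lambda=float(cfg["Lambda"]))
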