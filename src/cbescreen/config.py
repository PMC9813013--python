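"""Configuration loading and output writing.

Configs are YAML.  The ``parameters`` section mirrors the parameter tree (or
uses flat dot-paths); unknown keys are rejected by name.  A ``life_table``
entry may point at a two-column CSV (age, q_annual).  The ``run`` section
carries execution settings (seed, iterations, perspective, horizon, output
directory).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .params import LifeTable, ModelParameters, ParameterError, get_path, set_path

__all__ = ["RunConfig", "load_config", "load_life_table", "load_dfs_events",
           "save_params", "write_outputs", "config_hash"]


@dataclass
class RunConfig:
    """Execution settings parsed from the ``run`` config section."""

    seed: int | None = None
    n_iterations: int = 2000
    perspective: str = "public_payer"
    horizon_months: int | None = None
    out_dir: str = "outputs"

    _KNOWN = ("seed", "n_iterations", "perspective", "horizon_months", "out_dir")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        for k in d:
            if k not in cls._KNOWN:
                raise ParameterError(f"unknown run-config key {k!r}")
        return cls(**d)


def _flatten(prefix: str, node) -> list[tuple[str, object]]:
    if isinstance(node, dict):
        out = []
        for k, v in node.items():
            out.extend(_flatten(f"{prefix}{k}.", v))
        return out
    return [(prefix[:-1], node)]


def load_life_table(path) -> LifeTable:
    """Two-column delimited table: age (integer years), q_annual."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ParameterError(f"life table {path} needs two columns (age, q_annual)")
    return LifeTable(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


def load_dfs_events(path) -> pd.DataFrame:
    """Three-column event table: time_months, event (0/1), type (nm/mbc/na)."""
    df = pd.read_csv(path)
    missing = {"time_months", "event"} - set(df.columns)
    if missing:
        raise ParameterError(f"event table {path} missing columns {sorted(missing)}")
    if "type" not in df.columns:
        df["type"] = "na"
    return df


def load_config(path) -> tuple[ModelParameters, RunConfig]:
    """Load defaults merged with overrides; re-validate the final set.

    An empty (or missing-section) config returns the exact packaged defaults.
    """
    from .synthetic import default_parameters

    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text) or {}
    except yaml.YAMLError as e:
        raise ParameterError(f"cannot parse config {path}: {e}") from e
    if not isinstance(doc, dict):
        raise ParameterError(f"config {path} must be a mapping at top level")
    for key in doc:
        if key not in ("parameters", "run", "life_table_csv"):
            raise ParameterError(f"unknown top-level config key {key!r}")

    params = default_parameters()
    if "life_table_csv" in doc:
        params.life_table = load_life_table(doc["life_table_csv"])
    overrides = doc.get("parameters") or {}
    if not isinstance(overrides, dict):
        raise ParameterError("'parameters' section must be a mapping")
    for dotted, value in _flatten("", overrides):
        params = set_path(params, dotted, value)
    params.validate()
    run = RunConfig.from_dict(doc.get("run") or {})
    return params, run


def save_params(params: ModelParameters, path) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))


def config_hash(params: ModelParameters) -> str:
    """Stable hash of the full parameter set, for run metadata."""
    blob = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_outputs(results: dict, out_dir, seed=None, params: ModelParameters | None = None) -> list[Path]:
    """Write result tables as headed CSVs plus a YAML run-metadata file.

    ``results`` maps a table name to a DataFrame (or to an object exposing
    ``summary_frame``/``to_frame``).  Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in results.items():
        if hasattr(obj, "summary_frame"):
            df = obj.summary_frame()
        elif hasattr(obj, "to_frame") and not isinstance(obj, pd.Series):
            df = obj.to_frame()
        elif isinstance(obj, pd.DataFrame):
            df = obj
        else:
            raise ParameterError(f"cannot serialise output {name!r} of type {type(obj)}")
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        written.append(p)
    from . import __version__

    meta = {"seed": seed, "version": __version__}
    if params is not None:
        meta["config_hash"] = config_hash(params)
    mp = out / "run_metadata.yaml"
    mp.write_text(yaml.safe_dump(meta, sort_keys=True))
    written.append(mp)
    return written
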