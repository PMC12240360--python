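"""Configuration files, structured outputs and run manifests.

Model parameters and ensemble specs are read from flat key-value TOML or
YAML files; absent keys fall back to the baseline defaults and unknown
keys are rejected so typos cannot silently change an experiment.  Every
CLI run writes its outputs as tidy CSV plus a JSON metadata sidecar and
records them in a :class:`RunManifest`, which captures the command, the
configuration snapshot and every seed before execution — enough to rerun
any figure bit-identically.
"""

from __future__ import annotations

import datetime as _dt
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .generate import EnsembleSpec
from .model import ModelParams, TABLE_DEFAULTS

__all__ = [
    "RunManifest",
    "load_config",
    "params_from_config",
    "ensemble_from_config",
    "params_to_config",
    "save_config",
    "write_results",
]

#: Keys accepted in a model-parameter config (scalar entries; ``ri``,
#: ``ui``, ``di`` may be scalars, broadcast over exploiters, or lists).
PARAM_KEYS = set(TABLE_DEFAULTS) | {"n", "g", "beta", "ri", "ui", "di"}

ENSEMBLE_KEYS = {"N", "beta", "g", "connectance_grid", "n_param_draws",
                 "n_init_draws", "base_seed", "T_total", "T_check",
                 "extinction_threshold"}

#: Documented valid ranges enforced under strict validation.
STRICT_RANGES = {"g": (0.05, 0.5), "beta": (0.0, 0.18)}


def load_config(path: str | Path) -> dict:
    """Parse a flat TOML or YAML mapping."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    elif path.suffix in (".yaml", ".yml"):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        raise ValueError(f"unsupported config format: {path.suffix}")
    if not isinstance(data, dict):
        raise ValueError("config must be a flat key-value mapping")
    return data


def params_from_config(source: str | Path | dict, *,
                       strict: bool = False) -> ModelParams:
    """Build :class:`ModelParams` from a config, applying baseline
    defaults for absent keys and rejecting unknown ones.

    ``strict=True`` additionally enforces the documented study ranges
    (``g`` in [0.05, 0.5], ``beta`` in [0, 0.18]).
    """
    data = dict(source) if isinstance(source, dict) else load_config(source)
    unknown = set(data) - PARAM_KEYS
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    if strict:
        for key, (lo, hi) in STRICT_RANGES.items():
            if key in data and not (lo <= float(data[key]) <= hi):
                raise ValueError(
                    f"{key}={data[key]} outside documented range [{lo}, {hi}]")
    n = int(data.pop("n", 1))
    beta = data.pop("beta", 0.0)
    kw = {}
    for key in ("ri", "ui", "di"):
        if key in data:
            v = data.pop(key)
            kw[key] = np.full(n, float(v)) if np.isscalar(v) else np.asarray(v, float)
    for key, val in data.items():
        kw[key] = float(val)
    return ModelParams(n=n, beta=beta, **kw)


def ensemble_from_config(source: str | Path | dict) -> EnsembleSpec:
    """Build an :class:`EnsembleSpec`, rejecting unknown keys."""
    data = dict(source) if isinstance(source, dict) else load_config(source)
    unknown = set(data) - ENSEMBLE_KEYS
    if unknown:
        raise ValueError(f"unknown ensemble keys: {sorted(unknown)}")
    if "connectance_grid" in data:
        data["connectance_grid"] = tuple(float(c) for c in data["connectance_grid"])
    return EnsembleSpec(**data)


def params_to_config(params: ModelParams) -> dict:
    """Flatten a parameter set to a round-trippable config mapping."""
    out = {"n": params.n, "g": params.g}
    for key in TABLE_DEFAULTS:
        out[key] = getattr(params, key)
    out["ri"] = params.ri.tolist()
    out["ui"] = params.ui.tolist()
    out["di"] = params.di.tolist()
    off = params.beta[~np.eye(params.n + 1, dtype=bool)]
    if off.size and np.allclose(off, off.flat[0]):
        out["beta"] = float(off.flat[0]) if off.size else 0.0
    else:
        out["beta"] = params.beta.tolist()
    return out


def save_config(data: dict, path: str | Path) -> None:
    """Write a config mapping as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class RunManifest:
    """Reproducibility record written alongside every CLI run."""

    command: str
    config: dict
    base_seed: int | None
    replicate_seeds: list = field(default_factory=list)
    version: str = __version__
    started: str = field(
        default_factory=lambda: _dt.datetime.now().isoformat(timespec="seconds"))
    outputs: list[str] = field(default_factory=list)

    def add_output(self, path: str | Path) -> None:
        self.outputs.append(str(path))

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=_jsonable)
        self.add_output(path) if str(path) not in self.outputs else None


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_results(result, path: str | Path, *, fmt: str = "csv",
                  metadata: dict | None = None,
                  manifest: RunManifest | None = None) -> list[Path]:
    """Write a result object as tidy CSV (or JSON) plus a metadata sidecar.

    Supported results: pandas DataFrames, persistence surfaces (summary +
    replicate manifest), time series (long format), plain mappings.
    Returns the list of files written.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_df(df: pd.DataFrame, p: Path):
        if fmt == "csv":
            df.to_csv(p.with_suffix(".csv"), index=False)
            written.append(p.with_suffix(".csv"))
        elif fmt == "json":
            df.to_json(p.with_suffix(".json"), orient="records", indent=2)
            written.append(p.with_suffix(".json"))
        else:
            raise ValueError("fmt must be 'csv' or 'json'")

    from .dynamics import TimeSeries          # local import: avoid cycle
    from .persistence import PersistenceSurface

    if isinstance(result, pd.DataFrame):
        _write_df(result, path)
    elif isinstance(result, PersistenceSurface):
        _write_df(result.summary, path)
        _write_df(result.replicates, path.with_name(path.stem + "_replicates"))
    elif isinstance(result, TimeSeries):
        _write_df(result.to_frame(), path)
    elif isinstance(result, dict):
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(result, fh, indent=2, default=_jsonable)
        written.append(path.with_suffix(".json"))
    else:
        raise TypeError(f"unsupported result type {type(result)}")

    if metadata is not None:
        side = path.with_name(path.stem + "_meta.json")
        with open(side, "w") as fh:
            json.dump(metadata, fh, indent=2, default=_jsonable)
        written.append(side)
    if manifest is not None:
        for p in written:
            manifest.add_output(p)
    return written
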