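"""TSV/JSON serialization and config round-tripping.

TSV dialect: tab-separated, '.' decimal, '#'-prefixed metadata header
lines.  Nested summaries go to JSON.  Configs round-trip through YAML.
"""

from __future__ import annotations

import dataclasses
import json
import math
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import IO, Union

import pandas as pd
import yaml

from .analytic import AccumulationTrajectory, EquilibriumInterval
from .ibm import SimConfig, SimRecord
from .params import ModelParams

try:
    _VERSION = version("senevo")
except PackageNotFoundError:  # pragma: no cover - editable-install oddity
    _VERSION = "unknown"


def _meta_lines(meta: dict) -> str:
    return "".join(f"# {k}={v}\n" for k, v in {"senevo": _VERSION, **meta}.items())


def _open(target: Union[str, Path, IO], mode: str = "w"):
    if hasattr(target, "write"):
        return target, False
    return open(target, mode), True


def write_table(df: pd.DataFrame, target, meta: dict | None = None) -> None:
    """Write a DataFrame as '#'-headed TSV."""
    fh, close = _open(target)
    try:
        fh.write(_meta_lines(meta or {}))
        df.to_csv(fh, sep="\t", index=False)
    finally:
        if close:
            fh.close()


def write_trajectory(traj: AccumulationTrajectory, target) -> None:
    """Trajectory as TSV (columns step, X) with params in the header."""
    meta = dataclasses.asdict(traj.params)
    meta["terminated_reason"] = traj.terminated_reason
    write_table(traj.to_frame(), target, meta)


def interval_dict(iv: EquilibriumInterval, params: ModelParams) -> dict:
    return {
        "params": dataclasses.asdict(params),
        "lower": iv.lower,
        "upper": iv.upper,
        "width": iv.width,
    }


def write_interval(iv: EquilibriumInterval, params: ModelParams, target) -> None:
    fh, close = _open(target)
    try:
        json.dump(interval_dict(iv, params), fh, indent=2)
        fh.write("\n")
    finally:
        if close:
            fh.close()


def record_frame(rec: SimRecord) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": rec.times,
            "census": rec.census,
            "n_segregating": rec.n_segregating,
            "fixed_max_age": rec.fixed_max_age,
            "mean_fecundity_weight": rec.mean_fecundity_weight,
        }
    )


def write_record(rec: SimRecord, tsv_target, json_target=None) -> None:
    """SimRecord time series as TSV plus an optional JSON summary."""
    write_table(record_frame(rec), tsv_target, {"seed": rec.config.seed})
    if json_target is not None:
        fh, close = _open(json_target)
        try:
            summary = rec.summary()
            summary["fixation_events"] = [
                {"locus_id": i, "time": t, "expression_trigger": a}
                for i, t, a in rec.fixation_events
            ]
            summary["config"] = config_dict(rec.config)
            json.dump(_jsonable(summary), fh, indent=2)
            fh.write("\n")
        finally:
            if close:
                fh.close()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and math.isinf(obj):
        return "inf" if obj > 0 else "-inf"
    return obj


def config_dict(config) -> dict:
    d = dataclasses.asdict(config)
    d.pop("initial_loci", None)
    return d


def dump_config(config, target) -> None:
    """Dump a ModelParams or SimConfig to YAML (round-trippable)."""
    kind = "model" if isinstance(config, ModelParams) else "sim"
    fh, close = _open(target)
    try:
        yaml.safe_dump({"kind": kind, **_jsonable(config_dict(config))}, fh)
    finally:
        if close:
            fh.close()


def load_config(source) -> Union[ModelParams, SimConfig]:
    """Parse a YAML config written by :func:`dump_config`.

    Unknown keys are rejected; 'inf' strings are revived as floats.
    """
    fh, close = _open(source, "r")
    try:
        data = yaml.safe_load(fh)
    finally:
        if close:
            fh.close()
    if not isinstance(data, dict) or "kind" not in data:
        raise ValueError("config must be a mapping with a 'kind' key")
    kind = data.pop("kind")
    cls = {"model": ModelParams, "sim": SimConfig}.get(kind)
    if cls is None:
        raise ValueError(f"unknown config kind {kind!r}")
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for k, v in data.items():
        if v in ("inf", "-inf"):
            data[k] = math.inf if v == "inf" else -math.inf
    return cls(**data)
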