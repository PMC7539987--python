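"""Delimited-text input/output and flat key-value model configuration.

Every table written by the package is tab-separated with ``#``-prefixed
header lines carrying the package version, a configuration hash, and any
run metadata, so outputs are self-describing and reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import DataError, UsageError
from .types import (
    EnzymePHProfile,
    KineticModel,
    LightSchedule,
    LightToPH,
    PAMTrace,
    QuenchingParams,
    Segment,
)

__all__ = [
    "config_hash",
    "write_table",
    "read_table",
    "model_to_config",
    "model_from_config",
    "write_model_config",
    "read_model_config",
    "read_schedule",
    "write_schedule",
    "read_pam_trace",
]


def config_hash(params: dict) -> str:
    """Short stable hash of a parameter mapping."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    path = Path(path)
    lines = [f"# xcquench {__version__}"]
    meta = dict(meta or {})
    meta.setdefault("config_hash", config_hash(meta))
    for k, v in meta.items():
        lines.append(f"# {k}: {v}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            pos = fh.tell()
        df = pd.read_csv(fh, sep="\t")
    return df, meta


# --- flat key-value model configs -------------------------------------------

_MODEL_KEYS = ("k_de1", "k_de2", "k_ep", "dtt_inhibition", "species_label")
_PH_KEYS = ("ph_opt", "slope_acid", "slope_alkaline", "acid_offset", "species_label")
_LTP_KEYS = ("ph_dark", "ph_span", "half_sat", "tau")


def model_to_config(model: KineticModel) -> dict[str, float | str]:
    """Flatten a KineticModel into a key-value mapping (dotted group names)."""
    cfg: dict[str, float | str] = {}
    for k in _MODEL_KEYS:
        cfg[k] = getattr(model, k)
    for k in _PH_KEYS:
        cfg[f"ph_profile.{k}"] = getattr(model.ph_profile, k)
    for k in _LTP_KEYS:
        cfg[f"light_to_ph.{k}"] = getattr(model.light_to_ph, k)
    import dataclasses

    for f in dataclasses.fields(model.q_params):
        cfg[f"q_params.{f.name}"] = getattr(model.q_params, f.name)
    return cfg


def model_from_config(cfg: dict) -> KineticModel:
    cfg = dict(cfg)

    def group(prefix: str) -> dict:
        return {k.split(".", 1)[1]: v for k, v in cfg.items() if k.startswith(prefix + ".")}

    known = set(_MODEL_KEYS)
    for k in cfg:
        if "." in k:
            g = k.split(".", 1)[0]
            if g not in ("ph_profile", "light_to_ph", "q_params"):
                raise UsageError(f"unknown config group {g!r}")
        elif k not in known:
            raise UsageError(f"unknown config key {k!r}")
    try:
        return KineticModel(
            k_de1=float(cfg["k_de1"]), k_de2=float(cfg["k_de2"]),
            k_ep=float(cfg["k_ep"]),
            dtt_inhibition=float(cfg.get("dtt_inhibition", 0.0)),
            species_label=str(cfg.get("species_label", "")),
            ph_profile=EnzymePHProfile(**{
                k: (v if k == "species_label" else float(v))
                for k, v in group("ph_profile").items()}),
            light_to_ph=LightToPH(**{k: float(v) for k, v in group("light_to_ph").items()}),
            q_params=QuenchingParams(**{k: float(v) for k, v in group("q_params").items()}),
        )
    except (KeyError, TypeError) as exc:
        raise UsageError(f"incomplete or malformed model config: {exc}") from exc


def write_model_config(model: KineticModel, path, comment: str = "") -> None:
    lines = [f"# xcquench {__version__} kinetic model"]
    if comment:
        lines += [f"# {c}" for c in comment.splitlines()]
    for k, v in model_to_config(model).items():
        lines.append(f"{k} = {v!r}" if isinstance(v, str) else f"{k} = {v!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_model_config(path) -> KineticModel:
    path = Path(path)
    if not path.exists():
        raise DataError(f"model config not found: {path}")
    cfg: dict[str, str] = {}
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise UsageError(f"malformed config line: {raw!r}")
        k, v = (s.strip() for s in line.split("=", 1))
        cfg[k] = v.strip("'\"")
    return model_from_config(cfg)


def load_default_config(name: str) -> KineticModel:
    """Load one of the shipped per-species default model files."""
    from importlib.resources import files

    res = files("xcquench").joinpath(f"data/{name}.cfg")
    if not res.is_file():
        raise DataError(f"no shipped model config named {name!r}")
    cfg: dict[str, str] = {}
    for raw in res.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        k, v = (s.strip() for s in line.split("=", 1))
        cfg[k] = v.strip("'\"")
    return model_from_config(cfg)


# --- schedules & traces ------------------------------------------------------


def write_schedule(schedule: LightSchedule, path) -> None:
    doc = {
        "pulse_interval": schedule.pulse_interval,
        "pulse_irradiance": schedule.pulse_irradiance,
        "segments": [
            {"duration": s.duration, "irradiance": s.irradiance, "inhibitor": s.inhibitor}
            for s in schedule.segments
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_schedule(path) -> LightSchedule:
    path = Path(path)
    if not path.exists():
        raise DataError(f"schedule file not found: {path}")
    doc = yaml.safe_load(path.read_text())
    extra = set(doc) - {"pulse_interval", "pulse_irradiance", "segments"}
    if extra:
        raise UsageError(f"unknown schedule keys: {sorted(extra)}")
    try:
        segs = tuple(
            Segment(float(s["duration"]), float(s["irradiance"]),
                    bool(s.get("inhibitor", False)))
            for s in doc["segments"]
        )
        return LightSchedule(segments=segs,
                             pulse_interval=float(doc.get("pulse_interval", 60.0)),
                             pulse_irradiance=float(doc.get("pulse_irradiance", 5000.0)))
    except (KeyError, TypeError) as exc:
        raise UsageError(f"malformed schedule file: {exc}") from exc


def read_pam_trace(trace_path, schedule_path) -> PAMTrace:
    """PAM trace from a delimited table (time, fluorescence[, pulse]) plus a
    schedule sidecar.  Pulse times come from a 0/1 ``pulse`` column when
    present, else from the schedule's pulse raster."""
    df, _ = read_table(trace_path)
    schedule = read_schedule(schedule_path)
    if not {"time", "fluorescence"} <= set(df.columns):
        raise DataError("PAM trace table needs 'time' and 'fluorescence' columns")
    if "pulse" in df.columns:
        marked = df.loc[df["pulse"] > 0, "time"].to_numpy(float)
        # collapse consecutive marked samples into one pulse time (center)
        pulse_times = []
        if marked.size:
            splits = np.split(marked, np.where(np.diff(marked) > 1.0)[0] + 1)
            pulse_times = [float(np.mean(s)) for s in splits]
        pulse_times = np.asarray(pulse_times)
    else:
        pulse_times = schedule.pulse_times()
    return PAMTrace(time=df["time"].to_numpy(float),
                    fluorescence=df["fluorescence"].to_numpy(float),
                    schedule=schedule, pulse_times=pulse_times)
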