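"""File formats: event CSV with JSON sidecar, database JSON, configs.

CSV dialect: comma-separated UTF-8 with a header row
``time,O3,LPG_LNG,NOx,alcohol,smoke,VOC,CO,NH3`` and one row per second.
JSON is written with sorted keys so reruns diff cleanly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import OdorDatabase
from .sim import CHANNELS, ClassSpec, SensorFrame

CSV_HEADER = ("time",) + CHANNELS


def write_event_csv(frame: SensorFrame, path) -> None:
    """Write one event; label (if any) goes to a ``.json`` sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time": frame.times.astype(int)})
    for i, name in enumerate(frame.channels):
        df[name] = frame.values[i]
    df.to_csv(path, index=False)
    if frame.label is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        write_json({"label": frame.label}, sidecar)


def read_event_csv(path) -> SensorFrame:
    path = Path(path)
    df = pd.read_csv(path)
    if tuple(df.columns) != CSV_HEADER:
        raise ValueError(f"unexpected CSV header in {path}: {tuple(df.columns)}")
    sidecar = path.with_suffix(path.suffix + ".json")
    label = None
    if sidecar.exists():
        label = read_json(sidecar).get("label")
    values = np.vstack([df[name].to_numpy(float) for name in CHANNELS])
    return SensorFrame(times=df["time"].to_numpy(float), values=values, label=label)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def write_database(db: OdorDatabase, path) -> None:
    write_json(db.to_dict(), path)


def read_database(path) -> OdorDatabase:
    return OdorDatabase.from_dict(read_json(path))


def spec_to_dict(spec: ClassSpec) -> dict:
    return {
        "label": spec.label,
        "amplitude": np.asarray(spec.amplitude).tolist(),
        "rise_time": np.asarray(spec.rise_time).tolist(),
        "baseline": np.asarray(spec.baseline).tolist(),
        "saturation": np.asarray(spec.saturation).tolist(),
        "drift": spec.drift,
        "noise_sd": spec.noise_sd,
    }


def spec_from_dict(d: dict) -> ClassSpec:
    return ClassSpec(**d)


def load_specs(path) -> list[ClassSpec]:
    """Load ClassSpecs from a YAML/JSON file (a list of spec mappings)."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if isinstance(data, dict):
        data = data.get("classes", [])
    if not isinstance(data, list):
        raise ValueError("spec file must contain a list of class specs")
    return [spec_from_dict(d) for d in data]


def load_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
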