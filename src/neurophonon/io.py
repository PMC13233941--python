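"""Recording and model file formats.

Recordings are plain CSV (first column ``time_s``, then one column per
channel in uV, 17 significant digits, '.' decimal, LF endings) with a JSON
sidecar ``<name>.json`` carrying {fs_hz, channels, units, seed, model_hash}.
Models and simulation configs round-trip through YAML/JSON mappings.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulator import MultichannelRecording, NetworkModel

__all__ = [
    "write_recording",
    "read_recording",
    "save_model",
    "load_model",
    "sidecar_path",
]


def sidecar_path(csv_path: str | Path) -> Path:
    p = Path(csv_path)
    return p.with_suffix(".json")


def write_recording(recording: MultichannelRecording, csv_path: str | Path) -> Path:
    """Write the recording as CSV + JSON sidecar; returns the CSV path.

    Float64 samples are printed with 17 significant digits, so a
    write -> read round trip is bit-exact.
    """
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"time_s": recording.times})
    for name, row in zip(recording.channels, recording.data):
        df[name] = row
    df.to_csv(csv_path, index=False, float_format="%.17g", lineterminator="\n")
    sidecar = {
        "fs_hz": recording.fs,
        "channels": list(recording.channels),
        "units": recording.meta.get("units", "uV"),
        "seed": recording.meta.get("seed"),
        "model_hash": recording.meta.get("model_hash"),
    }
    sidecar_path(csv_path).write_text(json.dumps(sidecar, indent=1) + "\n")
    return csv_path


def read_recording(csv_path: str | Path) -> MultichannelRecording:
    """Read a CSV + sidecar recording, cross-checking the sampling rate.

    The sidecar must exist; its fs_hz must match the median time step of the
    CSV time column to 1 ppm, and its channel list must match the columns.
    """
    csv_path = Path(csv_path)
    sc_path = sidecar_path(csv_path)
    if not sc_path.exists():
        raise FileNotFoundError(
            f"missing JSON sidecar {sc_path} for recording {csv_path}"
        )
    sidecar = json.loads(sc_path.read_text())
    df = pd.read_csv(csv_path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ValueError(f"{csv_path} has no 'time_s' column")
    if df.isna().any().any():
        raise ValueError(f"{csv_path} contains missing values (ragged rows?)")
    fs = float(sidecar["fs_hz"])
    t = df["time_s"].to_numpy()
    if t.size >= 2:
        dt = float(np.median(np.diff(t)))
        if abs(dt * fs - 1.0) > 1e-6:
            raise ValueError(
                f"sampling-rate mismatch: sidecar fs={fs} Hz but CSV time step "
                f"{dt:g} s implies fs={1.0 / dt:g} Hz"
            )
    channels = list(sidecar["channels"])
    missing = [c for c in channels if c not in df.columns]
    if missing:
        raise ValueError(f"sidecar channels {missing} absent from {csv_path}")
    data = df[channels].to_numpy().T
    meta = {
        "units": sidecar.get("units", "uV"),
        "seed": sidecar.get("seed"),
        "model_hash": sidecar.get("model_hash"),
        "source": str(csv_path),
    }
    return MultichannelRecording(fs=fs, channels=channels, data=data, meta=meta)


def save_model(model: NetworkModel, path: str | Path) -> Path:
    """Serialise a network model to YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    d = model.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=1) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    return path


def load_model(path: str | Path) -> NetworkModel:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return NetworkModel.from_dict(d)
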