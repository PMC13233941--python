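"""One-shot report bundle: basis, spectra, metrics, energy, personality, manifest.

``run_report`` ties the analysis modules together for a consistent
(model, recording) pair and writes one output directory.  All numeric
artefacts are deterministic functions of (model, recording, seed), so a
rerun with the same inputs reproduces them bit-identically; only the
manifest carries a timestamp.
"""

from __future__ import annotations

import hashlib
import json
import sys
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .metrics import (
    BANDS,
    analytic_band_signal,
    band_power,
    coherence_entropy,
    coherence_matrix,
    plv_matrix,
    welch_psd,
)
from .personality import (
    DEFAULT_THRESHOLDS,
    classify_personality,
    coordinates_from_model,
)
from .phonon import build_basis, energy_report, project_recording
from .simulator import MultichannelRecording, NetworkModel
from .spectra import default_gamma, spectral_result

__all__ = ["run_report"]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def run_report(
    model: NetworkModel,
    recording: MultichannelRecording,
    out_dir: str | Path,
    bands: tuple[str, ...] = ("alpha",),
    gamma: float | None = None,
    seed: int = 0,
    freq_hz: np.ndarray | None = None,
) -> dict:
    """Run the full analysis pipeline and write the report directory.

    Emits basis.json + eigenvectors.csv, spectra.csv, metrics.csv,
    energy.json, personality.json and manifest.json.  Returns a summary
    dict with the personality label and key numbers.
    """
    if recording.n_channels != model.n_channels:
        raise ValueError("model/recording channel counts differ")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    # --- phonon basis -----------------------------------------------------
    basis = build_basis(model)
    _write_json(out / "basis.json", basis.to_dict())
    pd.DataFrame(
        basis.modes,
        index=recording.channels,
        columns=[f"mode{ell}" for ell in range(basis.n_modes)],
    ).to_csv(out / "eigenvectors.csv", float_format="%.17g")
    files += ["basis.json", "eigenvectors.csv"]

    # --- analytic spectra (tidy CSV) --------------------------------------
    if freq_hz is None:
        freq_hz = np.linspace(0.0, recording.fs / 2.0, 257)
    g = default_gamma(model) if gamma is None else gamma
    sres = spectral_result(basis, model, freq_hz, g)
    rows = []
    for ell in range(basis.n_modes):
        for fi, f in enumerate(sres.freq):
            rows.append(("mode_psd", ell, ell, f, sres.mode_psd[ell, fi]))
    for j in range(model.n_channels):
        for k in range(j, model.n_channels):
            for fi, f in enumerate(sres.freq):
                rows.append(("cross", j, k, f, float(sres.cross[j, k, fi].real)))
                rows.append(("coherence", j, k, f, float(sres.coherence[j, k, fi])))
    pd.DataFrame(rows, columns=["kind", "i", "j", "freq_hz", "value"]).to_csv(
        out / "spectra.csv", index=False, float_format="%.17g"
    )
    files.append("spectra.csv")

    # --- empirical metrics (tidy CSV + JSON summary) ----------------------
    mrows = []
    summary_metrics: dict = {}
    freq_w, psd = welch_psd(recording)
    for bname in bands:
        band = BANDS[bname]
        zb = analytic_band_signal(recording, band, trim=True)
        bp = band_power(freq_w, psd, band)
        for j, ch in enumerate(recording.channels):
            mrows.append((bname, "band_power", ch, ch, float(bp[j])))
        if model.n_channels > 1:
            pm = plv_matrix(zb)
            cm = coherence_matrix(zb)
            for j in range(model.n_channels):
                for k in range(j + 1, model.n_channels):
                    mrows.append((bname, "plv", recording.channels[j],
                                  recording.channels[k], float(pm[j, k])))
                    mrows.append((bname, "coherence", recording.channels[j],
                                  recording.channels[k], float(cm[j, k])))
            h = coherence_entropy(cm)
            summary_metrics[f"coherence_entropy_{bname}"] = h
            mrows.append((bname, "coherence_entropy", "*", "*", h))
        summary_metrics[f"band_power_{bname}_mean"] = float(bp.mean())
    pd.DataFrame(
        mrows, columns=["band", "metric", "channel_i", "channel_j", "value"]
    ).to_csv(out / "metrics.csv", index=False, float_format="%.17g")
    files.append("metrics.csv")

    # --- energy and personality -------------------------------------------
    traj = project_recording(basis, model, recording)
    energy = energy_report(model, basis, recording, traj)
    erep = energy.to_dict()
    _write_json(out / "energy.json", erep)
    files.append("energy.json")

    coords = coordinates_from_model(model, basis.Omega)
    label = classify_personality(coords)
    _write_json(out / "personality.json", {
        "label": label,
        "coordinates": coords.__dict__,
        "thresholds": DEFAULT_THRESHOLDS.to_dict(),
    })
    files.append("personality.json")

    # --- manifest ----------------------------------------------------------
    inventory = {}
    for name in files:
        inventory[name] = hashlib.sha256((out / name).read_bytes()).hexdigest()
    manifest = {
        "model_hash": model.content_hash(),
        "recording_meta": {k: v for k, v in recording.meta.items()
                           if isinstance(v, (str, int, float, type(None)))},
        "seed": seed,
        "bands": list(bands),
        "gamma": float(np.atleast_1d(g)[0]),
        "versions": {
            "neurophonon": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
        },
        "files": inventory,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    _write_json(out / "manifest.json", manifest)

    return {
        "label": label,
        "energy_total": energy.total,
        "files": files + ["manifest.json"],
        "out_dir": str(out),
        **summary_metrics,
    }
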