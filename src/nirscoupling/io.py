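"""Tidy CSV dialects and JSON sidecars for all pipeline artefacts.

One dialect everywhere: comma-separated, dot decimal, single header row,
UTF-8.  Concentration traces travel as (time_s, hbo2_uM, hhb_uM, oxcco_uM)
with the generating scenario / processing log in a ``<name>.json`` sidecar;
attenuation spectra as a matrix whose first column is wavelength_nm and whose
remaining columns are time points.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .spectral import AttenuationSeries
from .synthetic import ChromophoreSeries
from .preprocess import SignalSet, SIGNAL_NAMES

__all__ = [
    "write_chromophore_csv",
    "read_chromophore_csv",
    "write_attenuation_csv",
    "read_attenuation_csv",
    "write_signal_set",
    "read_signal_set",
    "write_results_csv",
    "read_results_csv",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_chromophore_csv(series: ChromophoreSeries, path) -> Path:
    path = Path(path)
    df = pd.DataFrame({
        "time_s": series.t,
        "hbo2_uM": series.hbo2,
        "hhb_uM": series.hhb,
        "oxcco_uM": series.oxcco,
    })
    df.to_csv(path, index=False)
    meta = {k: v for k, v in series.meta.items() if k != "residuals"}
    _sidecar(path).write_text(json.dumps(_jsonable({"fs": series.fs, "meta": meta}), indent=2))
    return path


def read_chromophore_csv(path) -> ChromophoreSeries:
    path = Path(path)
    df = pd.read_csv(path)
    required = {"time_s", "hbo2_uM", "hhb_uM", "oxcco_uM"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"{path.name}: missing columns {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    meta, fs = {}, None
    sc = _sidecar(path)
    if sc.exists():
        payload = json.loads(sc.read_text())
        fs = payload.get("fs")
        meta = payload.get("meta", {})
    if fs is None:
        if t.size < 2:
            raise ConfigurationError(f"{path.name}: cannot infer fs from one sample")
        fs = 1.0 / float(np.median(np.diff(t)))
    return ChromophoreSeries(
        t=t, hbo2=df["hbo2_uM"].to_numpy(float), hhb=df["hhb_uM"].to_numpy(float),
        oxcco=df["oxcco_uM"].to_numpy(float), fs=float(fs), meta=meta,
    )


def write_attenuation_csv(atten: AttenuationSeries, path) -> Path:
    path = Path(path)
    cols = {"wavelength_nm": atten.wavelengths}
    for j, tj in enumerate(atten.t):
        cols[f"t{tj:g}"] = atten.dA[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps({"t": _jsonable(atten.t), "units": "OD"}, indent=2))
    return path


def read_attenuation_csv(path) -> AttenuationSeries:
    path = Path(path)
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns:
        raise ConfigurationError(f"{path.name}: first column must be wavelength_nm")
    wl = df["wavelength_nm"].to_numpy(float)
    data_cols = [c for c in df.columns if c != "wavelength_nm"]
    sc = _sidecar(path)
    if sc.exists():
        t = np.asarray(json.loads(sc.read_text())["t"], dtype=float)
    else:
        t = np.array([float(c.lstrip("t")) for c in data_cols])
    return AttenuationSeries(wavelengths=wl, t=t, dA=df[data_cols].to_numpy(float))


def write_signal_set(s: SignalSet, path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"time_s": s.t, **{f"{n}_uM": s.signals[n] for n in SIGNAL_NAMES}})
    df.to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps(_jsonable({
        "fs": s.fs, "processing_log": s.processing_log,
        "meta": {k: v for k, v in s.meta.items() if k != "residuals"},
    }), indent=2))
    return path


def read_signal_set(path) -> SignalSet:
    path = Path(path)
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(float)
    signals = {}
    for name in SIGNAL_NAMES:
        col = f"{name}_uM"
        if col not in df.columns:
            raise ConfigurationError(f"{path.name}: missing column {col}")
        signals[name] = df[col].to_numpy(float)
    log, meta, fs = [], {}, None
    sc = _sidecar(path)
    if sc.exists():
        payload = json.loads(sc.read_text())
        fs = payload.get("fs")
        log = payload.get("processing_log", [])
        meta = payload.get("meta", {})
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    return SignalSet(t=t, signals=signals, fs=float(fs), processing_log=log, meta=meta)


def write_results_csv(rows: pd.DataFrame, path) -> Path:
    path = Path(path)
    rows.to_csv(path, index=False)
    return path


def read_results_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
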