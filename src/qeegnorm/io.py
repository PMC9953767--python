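"""Reading and writing recordings and feature tables.

Two recording dialects are supported: EDF (read through MNE's reader) and a
delimited-text matrix with one column per electrode, mirroring the ASCII
export of clinical EEG systems.  The EDF writer here is a minimal 16-bit
implementation (one-second data records) used mainly so synthetic cohorts
can round-trip through the same files a clinic would produce.

Non-EEG columns/channels (e.g. an ECG lead) are dropped on read; channel
names are normalized to classical 10-20 labels, accepting the modern
T7/T8/P7/P8 aliases for T3/T4/T5/T6.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .montage import ELECTRODES_1020, MonopolarRecording

_MODERN_ALIASES = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}
_CANON = {e.lower(): e for e in ELECTRODES_1020}
_CANON.update({k.lower(): v for k, v in _MODERN_ALIASES.items()})


def _normalize_label(raw: str) -> str | None:
    name = raw.strip()
    for prefix in ("EEG ", "eeg "):
        if name.startswith(prefix):
            name = name[len(prefix):]
    name = name.split("-")[0].strip()
    return _CANON.get(name.lower())


def _pick_electrodes(labels: Sequence[str], data: np.ndarray
                     ) -> tuple[list[str], np.ndarray]:
    found: dict[str, np.ndarray] = {}
    for i, raw in enumerate(labels):
        canon = _normalize_label(raw)
        if canon is not None and canon not in found:
            found[canon] = data[i]
    missing = [e for e in ELECTRODES_1020 if e not in found]
    if missing:
        raise ValueError(f"recording is missing electrode(s): {missing}")
    return list(ELECTRODES_1020), np.stack([found[e] for e in ELECTRODES_1020])


# ---------------------------------------------------------------------------
# delimited text

def write_text_recording(rec: MonopolarRecording, path, sep: str = "\t",
                         include_dummy_ecg: bool = False,
                         fmt: str = "%.4f") -> None:
    """Matrix export: a '# fs=... age=...' comment, a header of electrode
    labels, then one row per sample (µV)."""
    path = Path(path)
    labels = list(rec.labels)
    data = rec.samples
    if include_dummy_ecg:
        labels = labels + ["ECG"]
        data = np.vstack([data, _dummy_ecg(rec.n_times, rec.fs)])
    header = f"# fs={rec.fs:g}"
    if rec.subject_age is not None:
        header += f" age={rec.subject_age:g}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        fh.write(sep.join(labels) + "\n")
        np.savetxt(fh, data.T, fmt=fmt, delimiter=sep)


def read_text_recording(path, fs: float | None = None,
                        age: float | None = None) -> MonopolarRecording:
    """Read a delimited-text matrix (TSV or CSV, header row of labels)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    skip = 0
    if first.startswith("#"):
        skip = 1
        for token in first.lstrip("#").split():
            key, _, value = token.partition("=")
            if key == "fs" and fs is None:
                fs = float(value)
            elif key == "age" and age is None:
                age = float(value)
    if fs is None:
        raise ValueError(
            f"{path}: sampling rate not in file header; pass fs explicitly"
        )
    df = pd.read_csv(path, sep=None, engine="python", skiprows=skip)
    labels, data = _pick_electrodes(list(df.columns), df.to_numpy(float).T)
    return MonopolarRecording(labels, data, fs, subject_age=age)


# ---------------------------------------------------------------------------
# EDF

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: MonopolarRecording, path,
              include_dummy_ecg: bool = False) -> None:
    """Minimal 16-bit EDF writer with one-second data records.

    The sampling rate must be an integer; the record is truncated to whole
    seconds.  The subject's age, when known, is stored in the patient field
    as an ``age_<years>`` token.
    """
    path = Path(path)
    fs = rec.fs
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(fs)
    labels = list(rec.labels)
    data = rec.samples
    if include_dummy_ecg:
        labels = labels + ["ECG"]
        data = np.vstack([data, _dummy_ecg(rec.n_times, rec.fs)])
    n_rec = data.shape[1] // spr
    if n_rec < 1:
        raise ValueError("record shorter than one EDF data record (1 s)")
    data = data[:, : n_rec * spr]
    ns = len(labels)

    dig_min, dig_max = -32768, 32767
    phys_max = np.maximum(np.abs(data).max(axis=1) * 1.0001, 1.0)
    phys_max = np.array([float(f"{v:.6g}") for v in phys_max])
    phys_min = -phys_max

    patient = "X X X X"
    if rec.subject_age is not None:
        patient += f" age_{rec.subject_age:g}"

    header = b"".join([
        _edf_field("0", 8),
        _edf_field(patient, 80),
        _edf_field("Startdate 01-JAN-2000 synthetic", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (1 + ns), 8),
        _edf_field("", 44),
        _edf_field(n_rec, 8),
        _edf_field("1", 8),
        _edf_field(ns, 4),
    ])
    sig = b"".join([
        b"".join(_edf_field(l, 16) for l in labels),
        b"".join(_edf_field("AgAgCl electrode", 80) for _ in labels),
        b"".join(_edf_field("uV", 8) for _ in labels),
        b"".join(_edf_field(f"{v:g}", 8) for v in phys_min),
        b"".join(_edf_field(f"{v:g}", 8) for v in phys_max),
        b"".join(_edf_field(dig_min, 8) for _ in labels),
        b"".join(_edf_field(dig_max, 8) for _ in labels),
        b"".join(_edf_field("BP 0.5-70 Hz", 80) for _ in labels),
        b"".join(_edf_field(spr, 8) for _ in labels),
        b"".join(_edf_field("", 32) for _ in labels),
    ])
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            chunk = data[:, r * spr:(r + 1) * spr]
            dig = np.rint((chunk - phys_min[:, None]) * scale[:, None] + dig_min)
            dig = np.clip(dig, dig_min, dig_max).astype("<i2")
            fh.write(dig.tobytes())


def read_edf(path, age: float | None = None) -> MonopolarRecording:
    """Read an EDF(+) file via MNE, returning µV samples.

    If no age is given, an ``age_<years>`` token in the EDF patient field
    (as written by :func:`write_edf`) is honored.
    """
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads EEG in volts
    labels, picked = _pick_electrodes(raw.ch_names, data)
    if age is None:
        with open(path, "rb") as fh:
            patient = fh.read(88)[8:].decode("ascii", errors="replace")
        for token in patient.split():
            if token.startswith("age_"):
                age = float(token[4:])
                break
    return MonopolarRecording(labels, picked, float(raw.info["sfreq"]),
                              subject_age=age)


def read_recording(path, fs: float | None = None,
                   age: float | None = None) -> MonopolarRecording:
    """Dispatch on file suffix: .edf -> EDF, anything else -> delimited text."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path, age=age)
    return read_text_recording(path, fs=fs, age=age)


def _dummy_ecg(n: int, fs: float) -> np.ndarray:
    """A schematic 1 Hz ECG-like trace (format fidelity only, never analyzed)."""
    t = np.arange(n) / fs
    x = np.sin(2 * np.pi * 1.0 * t)
    return 600.0 * np.sign(x) * np.abs(x) ** 20


# ---------------------------------------------------------------------------
# feature tables

def write_features_csv(frame: pd.DataFrame, path) -> None:
    """Long-format feature export: (subject, feature, value)."""
    long = frame.reset_index(names="subject").melt(
        id_vars="subject", var_name="feature", value_name="value")
    long.to_csv(path, index=False)


def read_features_csv(path) -> pd.DataFrame:
    long = pd.read_csv(path)
    return long.pivot(index="subject", columns="feature", values="value")


def write_subject_json(features, path) -> None:
    """Per-subject JSON of the flattened feature vector."""
    series = features.to_series() if hasattr(features, "to_series") else features
    with open(path, "w") as fh:
        json.dump({k: float(v) for k, v in series.items()}, fh, indent=1)
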