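"""Read and write multi-lead ECG records in three dialects.

Supported dialects
------------------
``mat``
    One MATLAB variable ``ECG`` holding the fields ``data`` (n_leads x
    n_samples), ``fs``, ``label`` and ``leads`` — the layout of the
    CPSC-2018 distribution plus explicit metadata fields so round trips
    need no sidecar.
``wfdb``
    A minimal header+signal pair: ``<record>.hea`` text header (record
    name, lead count, sampling rate, sample count; one line per lead with
    gain and lead name; a ``#label:`` comment) and ``<record>.dat`` with
    interleaved little-endian int16 samples (format 16).
``csv``
    Rows = leads, one sample per column, with a JSON sidecar
    ``<record>.json`` holding ``{fs, lead_names, label}``. Missing lead
    names default to ``lead0``, ``lead1``, ...

Round trips are lossless up to float precision for ``mat`` and ``csv``;
the ``wfdb`` dialect quantizes to int16 at the stored gain.
"""

from __future__ import annotations

import csv as _csv
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.io as sio

from .records import ECGRecord, select_leads  # noqa: F401  (re-export)

_WFDB_GAIN = 1000.0  # int16 counts per millivolt


def write_record(record: ECGRecord, path, format: str = "mat") -> Path:
    """Write a record in the given dialect; returns the primary file path."""
    path = Path(path)
    if format == "mat":
        return _write_mat(record, path)
    if format == "wfdb":
        return _write_wfdb(record, path)
    if format == "csv":
        return _write_csv(record, path)
    raise ValueError(f"unknown format {format!r}; choose mat, wfdb or csv")


def read_record(path, format: str = "mat",
                label: Optional[str] = None) -> ECGRecord:
    """Read and validate one record.

    Parameters
    ----------
    path : path-like
        Primary file (.mat, .hea or .csv).
    format : {"mat", "wfdb", "csv"}
        Dialect to parse.
    label : str, optional
        Override/supply the rhythm label when the file carries none.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mat":
        rec = _read_mat(path)
    elif format == "wfdb":
        rec = _read_wfdb(path)
    elif format == "csv":
        rec = _read_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}; choose mat, wfdb or csv")
    if label is not None:
        rec.label = label
    if not rec.label:
        raise ValueError(
            f"{path}: no rhythm label stored and no label override supplied")
    return rec


# ---------------------------------------------------------------- MAT dialect

def _write_mat(record: ECGRecord, path: Path) -> Path:
    path = path.with_suffix(".mat")
    sio.savemat(path, {"ECG": {
        "data": record.signal,
        "fs": float(record.fs),
        "label": record.label,
        "leads": np.array(record.lead_names, dtype=object),
        "record_id": record.record_id,
    }})
    return path


def _read_mat(path: Path) -> ECGRecord:
    try:
        mat = sio.loadmat(path, squeeze_me=True, struct_as_record=False)
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise ValueError(f"{path}: not a readable MAT file ({exc})") from exc
    if "ECG" not in mat:
        raise ValueError(f"{path}: missing variable 'ECG'")
    ecg = mat["ECG"]
    for fieldname in ("data", "fs"):
        if not hasattr(ecg, fieldname):
            raise ValueError(f"{path}: ECG struct lacks field '{fieldname}'")
    data = np.atleast_2d(np.asarray(ecg.data, dtype=float))
    leads = getattr(ecg, "leads", None)
    if leads is None:
        lead_names = tuple(f"lead{i}" for i in range(data.shape[0]))
    else:
        lead_names = tuple(np.atleast_1d(leads).astype(str))
    if len(lead_names) != data.shape[0]:
        raise ValueError(
            f"{path}: {len(lead_names)} lead names for {data.shape[0]} "
            "signal rows")
    return ECGRecord(
        record_id=str(getattr(ecg, "record_id", path.stem)),
        signal=data,
        fs=float(ecg.fs),
        lead_names=lead_names,
        label=str(getattr(ecg, "label", "")),
    )


# --------------------------------------------------------------- CSV dialect

def _write_csv(record: ECGRecord, path: Path) -> Path:
    path = path.with_suffix(".csv")
    with open(path, "w", newline="") as fh:
        writer = _csv.writer(fh)
        for row in record.signal:
            writer.writerow(f"{v:.9g}" for v in row)
    sidecar = {
        "fs": record.fs,
        "lead_names": list(record.lead_names),
        "label": record.label,
        "record_id": record.record_id,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))
    return path


def _read_csv(path: Path) -> ECGRecord:
    with open(path, newline="") as fh:
        rows = [[float(v) for v in row] for row in _csv.reader(fh) if row]
    if not rows:
        raise ValueError(f"{path}: empty CSV")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows (lengths {sorted(widths)})")
    signal = np.asarray(rows, dtype=float)
    sidecar_path = path.with_suffix(".json")
    sidecar = {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
    if "fs" not in sidecar:
        raise ValueError(f"{path}: JSON sidecar with 'fs' required")
    lead_names = sidecar.get("lead_names") or [
        f"lead{i}" for i in range(signal.shape[0])]
    if len(lead_names) != signal.shape[0]:
        raise ValueError(
            f"{path}: {len(lead_names)} lead names for {signal.shape[0]} rows")
    return ECGRecord(
        record_id=str(sidecar.get("record_id", path.stem)),
        signal=signal,
        fs=float(sidecar["fs"]),
        lead_names=tuple(lead_names),
        label=str(sidecar.get("label", "")),
    )


# -------------------------------------------------------------- WFDB dialect

def _write_wfdb(record: ECGRecord, path: Path) -> Path:
    hea = path.with_suffix(".hea")
    dat = path.with_suffix(".dat")
    name = hea.stem
    n_sig, n_samp = record.signal.shape
    lines = [f"{name} {n_sig} {record.fs:g} {n_samp}"]
    for lead in record.lead_names:
        lines.append(f"{name}.dat 16 {_WFDB_GAIN:g} 16 0 0 0 0 {lead}")
    lines.append(f"#label: {record.label}")
    hea.write_text("\n".join(lines) + "\n")
    counts = np.clip(np.round(record.signal * _WFDB_GAIN),
                     -32768, 32767).astype("<i2")
    counts.T.reshape(-1).tofile(dat)  # interleaved samples
    return hea


def _read_wfdb(path: Path) -> ECGRecord:
    hea = path.with_suffix(".hea")
    lines = [ln.strip() for ln in hea.read_text().splitlines() if ln.strip()]
    head = lines[0].split()
    if len(head) < 4:
        raise ValueError(f"{hea}: malformed header line {lines[0]!r}")
    n_sig, fs, n_samp = int(head[1]), float(head[2]), int(head[3])
    lead_names, label = [], ""
    for ln in lines[1:]:
        if ln.startswith("#"):
            if ln[1:].strip().lower().startswith("label:"):
                label = ln.split(":", 1)[1].strip()
            continue
        lead_names.append(ln.split()[-1])
    if len(lead_names) != n_sig:
        raise ValueError(
            f"{hea}: header declares {n_sig} signals but lists "
            f"{len(lead_names)} lead lines")
    raw = np.fromfile(path.with_suffix(".dat"), dtype="<i2")
    if raw.size != n_sig * n_samp:
        raise ValueError(
            f"{path}: expected {n_sig * n_samp} samples, found {raw.size}")
    signal = raw.reshape(n_samp, n_sig).T.astype(float) / _WFDB_GAIN
    return ECGRecord(record_id=hea.stem, signal=signal, fs=fs,
                     lead_names=tuple(lead_names), label=label)


def write_dataset(records: Sequence[ECGRecord], directory,
                  format: str = "mat") -> list:
    """Write every record into `directory`; returns the file paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    return [write_record(r, directory / r.record_id, format=format)
            for r in records]
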