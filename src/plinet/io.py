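"""File I/O: EDF read/write, plain-text recordings and matrix export.

Reading EDF/EDF+ goes through MNE.  Writing uses a minimal 16-bit EDF
encoder implemented here (continuous recordings, physical units µV,
1-s data records), sufficient for round-tripping synthetic cohorts
through standard EEG readers.  A plain delimited-matrix format with a
JSON sidecar (sampling rate, labels, subject metadata) is provided as
the text-friendly alternative.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .montage import MONTAGE_25
from .preprocess import EEGRecording
from .stats import SubjectRecord


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, rec: EEGRecording) -> Path:
    """Write *rec* as a 16-bit EDF file (physical units µV, 1-s records).

    Samples beyond the last whole second are dropped (EDF stores whole
    data records only).
    """
    path = Path(path)
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records = rec.n_samples // fs
    if n_records == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    n_sig = rec.n_channels
    data = rec.data[:, : n_records * fs]

    phys_min = np.floor(data.min(axis=1))
    phys_max = np.ceil(data.max(axis=1))
    phys_max = np.where(phys_max <= phys_min, phys_min + 1, phys_max)
    dig_min, dig_max = -32768, 32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((data - phys_min[:, None]) / scale[:, None] + dig_min).astype("<i2")

    header = b"".join([
        _edf_field(0, 8),
        _edf_field(rec.subject_id or "X X X X", 80),
        _edf_field("Startdate 01-JAN-2000 X X X", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (1 + n_sig), 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field(1, 8),
        _edf_field(n_sig, 4),
    ])
    per_sig = b"".join([
        b"".join(_edf_field(lab, 16) for lab in rec.labels),
        b"".join(_edf_field("AgAgCl electrode", 80) for _ in rec.labels),
        b"".join(_edf_field("uV", 8) for _ in rec.labels),
        b"".join(_edf_field(f"{v:.8g}"[:8], 8) for v in phys_min),
        b"".join(_edf_field(f"{v:.8g}"[:8], 8) for v in phys_max),
        b"".join(_edf_field(dig_min, 8) for _ in rec.labels),
        b"".join(_edf_field(dig_max, 8) for _ in rec.labels),
        b"".join(_edf_field("", 80) for _ in rec.labels),
        b"".join(_edf_field(fs, 8) for _ in rec.labels),
        b"".join(_edf_field("", 32) for _ in rec.labels),
    ])
    with open(path, "wb") as fh:
        fh.write(header + per_sig)
        for r in range(n_records):
            fh.write(digital[:, r * fs:(r + 1) * fs].tobytes())
    return path


def read_edf(path: str | Path, montage: tuple[str, ...] = MONTAGE_25) -> EEGRecording:
    """Read an EDF/EDF+ file via MNE, matching labels to the montage.

    Labels are matched case-insensitively; channels outside the montage
    are dropped with a warning and the montage ordering is restored.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    by_lower = {lab.lower(): lab for lab in montage}
    keep, canonical = [], []
    dropped = []
    for name in raw.ch_names:
        key = name.strip().lower()
        if key in by_lower:
            keep.append(name)
            canonical.append(by_lower[key])
        else:
            dropped.append(name)
    if dropped:
        warnings.warn(f"dropping channels outside the montage: {dropped!r}", stacklevel=2)
    if not keep:
        raise ValueError("no montage channels found in EDF file")
    data = raw.get_data(picks=keep) * 1e6  # MNE loads volts
    order = sorted(range(len(canonical)), key=lambda i: montage.index(canonical[i]))
    return EEGRecording(
        data=data[order],
        fs=float(raw.info["sfreq"]),
        labels=tuple(canonical[i] for i in order),
        subject_id=Path(path).stem,
    )


def write_text_recording(path_stem: str | Path, rec: EEGRecording,
                         record: SubjectRecord | None = None) -> tuple[Path, Path]:
    """Write a recording as ``<stem>.tsv`` (samples x channels) plus a
    ``<stem>.json`` sidecar holding fs, labels and the subject record."""
    stem = Path(path_stem)
    tsv = stem.with_suffix(".tsv")
    meta = stem.with_suffix(".json")
    np.savetxt(tsv, rec.data.T, fmt="%.6f", delimiter="\t",
               header="\t".join(rec.labels), comments="")
    payload = {"fs": rec.fs, "labels": list(rec.labels), "subject_id": rec.subject_id}
    if record is not None:
        rec_dict = dataclasses.asdict(record)
        rec_dict["asm_list"] = list(rec_dict["asm_list"])
        payload["subject_record"] = {
            k: (None if isinstance(v, float) and np.isnan(v) else v)
            for k, v in rec_dict.items()
        }
    meta.write_text(json.dumps(payload, indent=1))
    return tsv, meta


def read_text_recording(path_stem: str | Path) -> tuple[EEGRecording, SubjectRecord | None]:
    """Read a ``write_text_recording`` pair back."""
    stem = Path(path_stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    data = np.loadtxt(stem.with_suffix(".tsv"), delimiter="\t", skiprows=1)
    rec = EEGRecording(
        data=data.T, fs=meta["fs"], labels=tuple(meta["labels"]),
        subject_id=meta.get("subject_id", stem.stem),
    )
    record = None
    if "subject_record" in meta:
        d = dict(meta["subject_record"])
        d["asm_list"] = tuple(d.get("asm_list") or ())
        for k, v in d.items():
            if v is None and k in ("va2", "age_of_onset", "duration", "seizure_duration_min"):
                d[k] = float("nan")
        record = SubjectRecord(**d)
    return rec, record


def write_connectivity(path_stem: str | Path, cm: ConnectivityMatrix) -> tuple[Path, Path]:
    """Write a PLI matrix as a labeled square TSV and a long edge list."""
    stem = Path(path_stem)
    square = stem.with_suffix(".tsv")
    frame = pd.DataFrame(cm.pli, index=cm.labels, columns=cm.labels)
    frame.to_csv(square, sep="\t", float_format="%.8f")
    rows = []
    n = len(cm.labels)
    for i in range(n):
        for j in range(i + 1, n):
            rows.append({
                "subject_id": cm.subject_id, "band": cm.band,
                "node_i": cm.labels[i], "node_j": cm.labels[j],
                "pli": cm.pli[i, j],
            })
    edges = stem.parent / (stem.name + "_edges.csv")
    pd.DataFrame(rows).to_csv(edges, index=False, float_format="%.8f")
    return square, edges
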