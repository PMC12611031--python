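"""Record and annotation I/O.

Two interchangeable on-disk representations are supported:

* flat CSV — one column per lead, amplitudes in mV, sample rate and metadata
  in ``#``-prefixed header comments; the lossless, human-readable default;
* WFDB-style record pairs — a text ``.hea`` header plus a format-16
  (little-endian int16) ``.dat`` signal file, enough for interchange with
  standard waveform tooling.  Amplitudes are quantised at the stated gain
  (default 200 adu/mV, 16-bit), so a WFDB round trip is exact only to the
  quantisation step.

Beat annotations travel as a CSV table (beat, q_idx, r_idx, s_idx).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import BeatAnnotations, ECGRecord

__all__ = [
    "write_csv_record",
    "read_csv_record",
    "write_wfdb_record",
    "read_wfdb_record",
    "write_annotations",
    "read_annotations",
]

_META_KEYS = ("subject_id", "group", "stage", "sample_rate")


def write_csv_record(record: ECGRecord, path: str | Path) -> Path:
    """Write one record as CSV with metadata header comments."""
    path = Path(path)
    buf = _io.StringIO()
    for key in _META_KEYS:
        buf.write(f"# {key}: {getattr(record, key)}\n")
    pd.DataFrame(record.samples.T, columns=record.lead_names).to_csv(buf, index=False)
    path.write_text(buf.getvalue())
    return path


def read_csv_record(path: str | Path) -> ECGRecord:
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return ECGRecord(
        subject_id=meta.get("subject_id", path.stem),
        group=meta.get("group", "control"),
        stage=meta.get("stage", "basal"),
        sample_rate=float(meta["sample_rate"]),
        lead_names=list(df.columns),
        samples=df.to_numpy().T,
    )


def write_wfdb_record(record: ECGRecord, record_dir: str | Path, gain: float = 200.0) -> Path:
    """Write ``<subject>_<stage>.hea`` + ``.dat`` (format 16, interleaved)."""
    record_dir = Path(record_dir)
    record_dir.mkdir(parents=True, exist_ok=True)
    name = f"{record.subject_id}_{record.stage}"
    n_sig, n_samp = record.samples.shape
    adc = np.clip(np.round(record.samples * gain), -32768, 32767).astype("<i2")
    (record_dir / f"{name}.dat").write_bytes(adc.T.reshape(-1).tobytes())
    lines = [f"{name} {n_sig} {record.sample_rate:g} {n_samp}"]
    for lead in record.lead_names:
        lines.append(f"{name}.dat 16 {gain:g}(0)/mV 16 0 0 0 0 {lead}")
    lines.append(f"# subject_id: {record.subject_id}")
    lines.append(f"# group: {record.group}")
    lines.append(f"# stage: {record.stage}")
    (record_dir / f"{name}.hea").write_text("\n".join(lines) + "\n")
    return record_dir / f"{name}.hea"


def read_wfdb_record(header_path: str | Path) -> ECGRecord:
    header_path = Path(header_path)
    lines = [ln.rstrip("\n") for ln in header_path.read_text().splitlines() if ln.strip()]
    meta = {}
    for ln in lines:
        if ln.startswith("#"):
            key, _, val = ln[1:].partition(":")
            meta[key.strip()] = val.strip()
    head = lines[0].split()
    n_sig, fs, n_samp = int(head[1]), float(head[2]), int(head[3])
    leads, gains = [], []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        if parts[1] != "16":
            raise ValueError(f"unsupported WFDB signal format {parts[1]!r} (only 16)")
        gains.append(float(parts[2].split("(")[0]))
        leads.append(parts[-1])
    dat = header_path.with_suffix(".dat")
    raw = np.frombuffer(dat.read_bytes(), dtype="<i2").reshape(n_samp, n_sig).T
    samples = raw.astype(float) / np.asarray(gains)[:, None]
    return ECGRecord(
        subject_id=meta.get("subject_id", header_path.stem),
        group=meta.get("group", "control"),
        stage=meta.get("stage", "basal"),
        sample_rate=fs,
        lead_names=leads,
        samples=samples,
    )


def write_annotations(ann: BeatAnnotations, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "beat": np.arange(len(ann)),
            "q_idx": ann.q_idx,
            "r_idx": ann.r_idx,
            "s_idx": ann.s_idx,
        }
    ).to_csv(path, index=False)
    return path


def read_annotations(path: str | Path) -> BeatAnnotations:
    df = pd.read_csv(path)
    return BeatAnnotations(
        q_idx=df["q_idx"].to_numpy(), r_idx=df["r_idx"].to_numpy(), s_idx=df["s_idx"].to_numpy()
    )
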