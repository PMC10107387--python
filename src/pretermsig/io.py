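"""Delimited-text record I/O: one file per patient plus a cohort manifest.

Record files carry ``# key=value`` header lines (patient_id, label, kind,
fs) followed by one sample per line; the manifest is a CSV with columns
patient_id, label, kind, path. Round-trips exactly at float repr precision.
"""

from __future__ import annotations

import os

import pandas as pd
import numpy as np

from .synth import Record

__all__ = ["write_record", "read_record", "write_cohort", "read_cohort"]


def write_record(record: Record, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# patient_id={record.patient_id}\n")
        fh.write(f"# label={record.label}\n")
        fh.write(f"# kind={record.signal_kind}\n")
        fh.write(f"# fs={'' if record.fs is None else repr(record.fs)}\n")
        for v in record.samples:
            fh.write(f"{float(v)!r}\n")


def read_record(path: str) -> Record:
    meta: dict[str, str] = {}
    samples: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
            else:
                samples.append(float(line))
    fs = float(meta["fs"]) if meta.get("fs") else None
    return Record(
        patient_id=meta["patient_id"],
        label=meta["label"],
        signal_kind=meta["kind"],
        samples=np.asarray(samples),
        fs=fs,
    )


def write_cohort(records: list[Record], out_dir: str) -> str:
    """Write one file per record plus ``manifest.csv``; returns manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for rec in records:
        fname = f"{rec.patient_id}_{rec.signal_kind}.txt"
        write_record(rec, os.path.join(out_dir, fname))
        rows.append(
            {
                "patient_id": rec.patient_id,
                "label": rec.label,
                "kind": rec.signal_kind,
                "path": fname,
            }
        )
    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str) -> list[Record]:
    base = os.path.dirname(manifest_path)
    table = pd.read_csv(manifest_path)
    return [read_record(os.path.join(base, p)) for p in table["path"]]
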