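"""Plain-text readers and writers: records, segments, features, manifests.

Records travel as a samples CSV (columns ``sample``; amplitudes in mV) with a
sidecar annotation CSV (columns ``onset,label``) named ``<stem>.ann.csv``.
WFDB-format inputs are recognized but not parsed (binary signal files); the
error message says how to convert.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .records import ChannelStack, EcgRecord, RhythmAnnotation, Segment

__all__ = [
    "read_record",
    "write_record",
    "write_segment_table",
    "write_channel_stack",
    "read_channel_stack",
    "write_features_csv",
    "read_features_csv",
    "write_manifest",
]


def _ann_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".ann.csv")


def read_record(path: str | Path, fs: float = 250.0,
                record_id: str | None = None) -> EcgRecord:
    """Load a record from a samples CSV (+ optional ``.ann.csv`` sidecar)."""
    path = Path(path)
    if path.suffix in (".hea", ".dat", ".atr"):
        raise ValueError(
            "WFDB binary records are not supported here; export the first "
            "channel to CSV (one 'sample' column, mV) with an .ann.csv sidecar"
        )
    df = pd.read_csv(path)
    col = "sample" if "sample" in df.columns else df.columns[0]
    annotations = []
    ann_file = _ann_path(path)
    if ann_file.exists():
        ann = pd.read_csv(ann_file)
        annotations = [
            RhythmAnnotation(onset=int(r.onset), label=str(r.label))
            for r in ann.itertuples()
        ]
    return EcgRecord(
        record_id=record_id or path.stem,
        samples=df[col].to_numpy(dtype=float),
        fs=fs,
        annotations=annotations,
    )


def write_record(record: EcgRecord, directory: str | Path) -> Path:
    """Write ``<record_id>.csv`` + ``<record_id>.ann.csv`` into a directory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    path = d / f"{record.record_id}.csv"
    pd.DataFrame({"sample": record.samples}).to_csv(path, index=False)
    pd.DataFrame(
        {"onset": [a.onset for a in record.annotations],
         "label": [a.label for a in record.annotations]}
    ).to_csv(_ann_path(path), index=False)
    return path


def write_segment_table(segments: list[Segment], path: str | Path) -> None:
    """Bookkeeping table: record_id, start, label, excluded, reason."""
    pd.DataFrame(
        {
            "record_id": [s.record_id for s in segments],
            "start": [s.start for s in segments],
            "label": [s.label for s in segments],
            "excluded": [s.excluded for s in segments],
            "reason": [s.exclusion_reason for s in segments],
        }
    ).to_csv(path, index=False)


def write_channel_stack(stack: ChannelStack, path: str | Path) -> None:
    pd.DataFrame(
        {"pecg": stack.pecg, "sh": stack.sh_signal, "nsh": stack.nsh_signal}
    ).to_csv(path, index=False)


def read_channel_stack(path: str | Path, label: int = 0,
                       record_id: str = "") -> ChannelStack:
    df = pd.read_csv(path)
    return ChannelStack(pecg=df["pecg"].to_numpy(), sh_signal=df["sh"].to_numpy(),
                        nsh_signal=df["nsh"].to_numpy(), label=label,
                        record_id=record_id)


def write_features_csv(features: np.ndarray, labels: np.ndarray,
                       path: str | Path, record_ids=None) -> None:
    """One row per segment: f0..f{d-1}, label [, record_id]."""
    feats = np.atleast_2d(np.asarray(features, dtype=float))
    df = pd.DataFrame(feats, columns=[f"f{i}" for i in range(feats.shape[1])])
    df["label"] = np.asarray(labels, dtype=int)
    if record_ids is not None:
        df["record_id"] = list(record_ids)
    df.to_csv(path, index=False)


def read_features_csv(path: str | Path):
    df = pd.read_csv(path)
    fcols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    feats = df[fcols].to_numpy(dtype=float)
    labels = df["label"].to_numpy(dtype=int)
    rids = df["record_id"].tolist() if "record_id" in df.columns else None
    return feats, labels, rids


def write_manifest(path: str | Path, **entries) -> None:
    """Reproducibility manifest (seeds, configs, versions) as JSON."""
    import shockadvice

    def default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if hasattr(obj, "__dataclass_fields__"):
            import dataclasses
            return dataclasses.asdict(obj)
        return str(obj)

    payload = {"shockadvice_version": shockadvice.__version__, **entries}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default)
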