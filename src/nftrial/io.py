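"""File formats: cohort CSV, session CSV + JSON sidecar, results JSON."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .signals import CHANNELS, NIRSRecording

__all__ = [
    "write_cohort", "read_cohort",
    "write_recording", "read_recording",
    "write_json", "read_json",
]


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """One row per participant; empty cells encode missing post scores."""
    cohort.to_csv(path, index=False, float_format="%.6g")


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_recording(rec: NIRSRecording, csv_path: str | Path) -> None:
    """Session CSV (time_s + 4 channels) with a .json schedule sidecar."""
    csv_path = Path(csv_path)
    rec.to_frame().to_csv(csv_path, index=False, float_format="%.6g")
    sidecar = {
        "participant": rec.participant,
        "day": rec.day,
        "fs": rec.fs,
        "schedule": [[k, s, e] for k, s, e in rec.schedule],
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(csv_path: str | Path) -> NIRSRecording:
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return NIRSRecording(
        participant=meta["participant"], day=int(meta["day"]),
        fs=float(meta["fs"]),
        channels={c: frame[c].to_numpy() for c in CHANNELS},
        schedule=[(k, float(s), float(e)) for k, s, e in meta["schedule"]])


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
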