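"""Delimited-text recording files and run configuration.

Recordings are stored as human-inspectable delimited text: commented
metadata lines (subject id, sampling rate), a header row, then one
sample per row (time, left, right, marker).  A nonzero marker flags a
trial-onset sample.  Comma and tab delimiters are auto-detected on read;
commas are written.  Finite values round-trip bit-identically because
floats are written with full ``repr`` precision.
"""

from __future__ import annotations

import json
from dataclasses import asdict, fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .preprocess import PipelineConfig, Recording

__all__ = ["read_recording", "write_recording", "load_config"]


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a Recording as commented-header delimited text with a marker column."""
    path = Path(path)
    fs = recording.sampling_rate
    marker = np.zeros(len(recording.time), dtype=int)
    t0 = recording.time[0]
    for trig in recording.triggers:
        marker[int(round((trig - t0) * fs))] = 1
    with open(path, "w") as fh:
        fh.write(f"# subject_id: {recording.subject_id}\n")
        fh.write(f"# sampling_rate: {repr(float(fs))}\n")
        fh.write("time,left,right,marker\n")
        for t, l, r, m in zip(recording.time, recording.left, recording.right, marker):
            fh.write(f"{repr(float(t))},{repr(float(l))},{repr(float(r))},{m}\n")


def read_recording(
    path: str | Path, triggers: Optional[Sequence[float]] = None
) -> Recording:
    """Parse a delimited recording file into a validated Recording.

    Triggers come from the nonzero entries of the marker column unless an
    explicit trigger list is given.  Malformed files raise errors naming
    the offending line where possible.
    """
    path = Path(path)
    meta: dict = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    sep = "\t" if "\t" in line else ","

    df = pd.read_csv(path, comment="#", sep=sep, float_precision="round_trip")
    required = {"time", "left", "right"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    time = df["time"].to_numpy(dtype=float)
    dt = np.diff(time)
    if np.any(dt <= 0):
        # +2: 1-based line numbering plus the column-header row
        bad = int(np.argmax(dt <= 0)) + header_lines + 2 + 1
        raise ValueError(f"{path}: time is not strictly increasing at line {bad}")

    if "sampling_rate" in meta:
        fs = float(meta["sampling_rate"])
        if len(dt) and abs(np.median(dt) - 1.0 / fs) > 1e-4 / fs:
            raise ValueError(
                f"{path}: declared sampling_rate {fs} Hz is inconsistent with "
                f"the time column (median dt {np.median(dt):.6g} s)"
            )
    else:
        fs = 1.0 / float(np.median(dt))

    if triggers is None:
        if "marker" in df.columns:
            triggers = time[df["marker"].to_numpy() != 0].tolist()
        else:
            triggers = []
    if not triggers:
        raise ValueError(f"{path}: no triggers (marker column empty and no list given)")
    return Recording(
        subject_id=meta.get("subject_id", path.stem),
        sampling_rate=fs,
        time=time,
        left=df["left"].to_numpy(dtype=float),
        right=df["right"].to_numpy(dtype=float),
        triggers=list(triggers),
    )


def load_config(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from YAML or JSON, rejecting unknown keys.

    List-valued window entries are converted to tuples.
    """
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if raw is None:
        return PipelineConfig()
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    cleaned = {
        k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
    }
    return PipelineConfig(**cleaned)
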