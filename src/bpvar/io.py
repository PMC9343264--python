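"""CSV storage for cohorts of blood-pressure traces.

One CSV per patient-channel (columns ``time_s``, ``<channel>_mmhg``,
``valid``; cleaned traces add ``removed`` and ``diff_excluded``) plus a
cohort manifest (``patient_id``, ``outcome``, ``channel``, ``duration_h``,
``n_samples``, ``file``).  Missing samples are explicit rows with
``valid = 0``, keeping the uniform-grid assumption checkable on disk.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Tuple

import numpy as np
import pandas as pd

from .errors import DataError
from .traces import BPTrace, CleanTrace

MANIFEST_NAME = "manifest.csv"
FLOAT_FORMAT = "%.10g"


def _value_column(channel: str) -> str:
    return f"{channel.lower()}_mmhg"


def write_trace_csv(trace: BPTrace, path: Path) -> None:
    cols = {
        "time_s": trace.t,
        _value_column(trace.channel): trace.x,
        "valid": trace.valid.astype(int),
    }
    if isinstance(trace, CleanTrace):
        cols["removed"] = trace.removed.astype(int)
        cols["diff_excluded"] = np.append(trace.diff_excluded, False).astype(int)
    pd.DataFrame(cols).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_trace_csv(path: Path, patient_id: str, channel: str) -> BPTrace:
    df = pd.read_csv(path)
    value_col = _value_column(channel)
    for col in ("time_s", value_col, "valid"):
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    t = df["time_s"].to_numpy(float)
    x = df[value_col].to_numpy(float)
    valid = df["valid"].to_numpy(bool)
    if "removed" in df.columns:
        return CleanTrace(
            patient_id, channel, t, x, valid,
            removed=df["removed"].to_numpy(bool),
            diff_excluded=df["diff_excluded"].to_numpy(bool)[:-1],
        )
    return BPTrace(patient_id, channel, t, x, valid)


def write_cohort(cohort: List[Tuple[BPTrace, str]], out_dir) -> Path:
    """Write per-patient CSVs plus the manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for trace, outcome in cohort:
        fname = f"{trace.patient_id}_{trace.channel.lower()}.csv"
        write_trace_csv(trace, out / fname)
        rows.append(
            {
                "patient_id": trace.patient_id,
                "outcome": outcome,
                "channel": trace.channel,
                "duration_h": trace.duration_s / 3600.0,
                "n_samples": trace.n,
                "file": fname,
            }
        )
    manifest = out / MANIFEST_NAME
    pd.DataFrame(rows).to_csv(manifest, index=False, float_format=FLOAT_FORMAT)
    return manifest


def read_cohort(in_dir, channel: str = None) -> List[Tuple[BPTrace, str]]:
    """Load a cohort from a manifest directory, optionally one channel only."""
    in_dir = Path(in_dir)
    manifest = in_dir / MANIFEST_NAME
    if not manifest.exists():
        raise DataError(f"no manifest found at {manifest}")
    df = pd.read_csv(manifest)
    required = {"patient_id", "outcome", "channel", "file"}
    if not required.issubset(df.columns):
        raise DataError(f"{manifest}: manifest must have columns {sorted(required)}")
    if channel is not None:
        df = df[df["channel"] == channel]
    if df.empty:
        raise DataError(f"{manifest}: manifest lists no traces" +
                        (f" for channel {channel}" if channel else ""))
    cohort = []
    for _, row in df.iterrows():
        trace = read_trace_csv(in_dir / row["file"], str(row["patient_id"]), row["channel"])
        cohort.append((trace, row["outcome"]))
    return cohort
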