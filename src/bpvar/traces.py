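"""Time-series containers for arterial blood-pressure records.

A :class:`BPTrace` is one patient-channel record on a uniform nominal grid
(1 Hz in the intended application): timestamps in seconds from record start,
pressures in mmHg, and a validity mask marking monitoring gaps as explicit
invalid samples rather than absent rows, so the uniform-grid assumption stays
checkable.

A :class:`CleanTrace` adds the two artifact annotations produced by
preprocessing: ``removed`` (points excluded by the moving-average threshold
filter, which thereby become gaps) and ``diff_excluded`` (successive-difference
positions excluded from ARV/SV by the 3-SD rule).  Position ``i`` of
``diff_excluded`` refers to the pair ``(i, i + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import List, Tuple

import numpy as np

from .errors import DataError

CHANNELS = ("SBP", "DBP", "MAP")


def bool_runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal contiguous runs of True in ``mask`` as half-open (start, stop) pairs."""
    m = np.asarray(mask, dtype=bool)
    edges = np.flatnonzero(np.diff(np.concatenate(([False], m, [False])).astype(np.int8)))
    return list(zip(edges[0::2].tolist(), edges[1::2].tolist()))


@dataclass
class BPTrace:
    """One patient-channel blood-pressure time series on a uniform grid."""

    patient_id: str
    channel: str
    t: np.ndarray  # seconds since record start, uniform spacing
    x: np.ndarray  # pressure, mmHg
    valid: np.ndarray  # False marks a monitoring gap

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.channel not in CHANNELS:
            raise DataError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if self.t.ndim != 1 or self.t.size < 2:
            raise DataError("t must be one-dimensional with at least 2 samples")
        if not (self.x.shape == self.t.shape == self.valid.shape):
            raise DataError("t, x and valid must have identical shapes")
        dt = self.t[1] - self.t[0]
        if dt <= 0 or not np.allclose(np.diff(self.t), dt, rtol=0, atol=1e-9 * max(dt, 1.0)):
            raise DataError("t must be strictly increasing with constant spacing")
        if not np.all(np.isfinite(self.x[self.valid])):
            raise DataError("x must be finite wherever valid is true")

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    @property
    def duration_s(self) -> float:
        """Nominal record length (one sampling interval per sample)."""
        return self.n * self.dt

    @property
    def clean_valid(self) -> np.ndarray:
        """Valid samples net of artifact removal (no removals on a raw trace)."""
        return self.valid


@dataclass
class CleanTrace(BPTrace):
    """An artifact-annotated trace produced by the preprocessing stage."""

    removed: np.ndarray = field(default=None)  # type: ignore[assignment]
    diff_excluded: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.removed is None:
            self.removed = np.zeros(self.n, dtype=bool)
        if self.diff_excluded is None:
            self.diff_excluded = np.zeros(max(self.n - 1, 0), dtype=bool)
        self.removed = np.asarray(self.removed, dtype=bool)
        self.diff_excluded = np.asarray(self.diff_excluded, dtype=bool)
        if self.removed.shape != self.t.shape:
            raise DataError("removed must match the sample grid")
        if self.diff_excluded.shape != (self.n - 1,):
            raise DataError("diff_excluded must have length n - 1")
        if np.any(self.removed & ~self.valid):
            raise DataError("removed must be a subset of originally valid positions")

    @property
    def clean_valid(self) -> np.ndarray:
        return self.valid & ~self.removed

    def segments(self) -> List[Tuple[int, int]]:
        """Maximal contiguous runs of usable samples, half-open index pairs."""
        return bool_runs(self.clean_valid)


def as_clean(trace: BPTrace) -> CleanTrace:
    """View a raw trace as a CleanTrace with empty artifact annotations."""
    if isinstance(trace, CleanTrace):
        return trace
    return CleanTrace(trace.patient_id, trace.channel, trace.t, trace.x, trace.valid)


def truncate(trace: BPTrace, seconds: float) -> BPTrace:
    """First ``seconds`` of a record; shorter records are returned whole."""
    if seconds <= 0:
        raise DataError("truncation length must be positive")
    k = int(np.searchsorted(trace.t, trace.t[0] + seconds - 1e-9 * trace.dt))
    k = max(k, 2)  # keep at least two samples so the grid stays defined
    kw = {}
    if isinstance(trace, CleanTrace):
        kw = dict(removed=trace.removed[:k], diff_excluded=trace.diff_excluded[: k - 1])
    return type(trace)(
        trace.patient_id, trace.channel, trace.t[:k], trace.x[:k], trace.valid[:k], **kw
    )
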