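"""Downsampling of 1 Hz blood-pressure records to coarser sampling intervals.

Two schemes are compared throughout the package:

* *instantaneous*: keep the first valid sample at or after each bin-start
  timestamp and discard everything else, mimicking intermittent readings.
  Variance of above-Nyquist content is preserved (aliased).
* *averaging*: replace each bin with the arithmetic mean of its valid
  samples, which acts as a low-pass (sinc) filter and suppresses
  above-Nyquist noise before it can alias.

Bins are half-open ``[k*interval, (k+1)*interval)`` anchored at the record
start, so no sample is counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError
from .traces import BPTrace

#: Sampling-interval grid (seconds) spanning 1 s to 30 min.
DEFAULT_GRID = (1, 5, 10, 30, 60, 120, 300, 600, 900, 1800)
METHODS = ("instantaneous", "averaging")
DEFAULT_MIN_COVERAGE = 0.5


@dataclass
class ResampledTrace:
    """A downsampled series; invalid bins had no (or too little) data."""

    patient_id: str
    channel: str
    interval_s: float
    method: str
    t: np.ndarray  # bin-start times, seconds
    x: np.ndarray
    valid: np.ndarray

    @property
    def n(self) -> int:
        return self.t.size


def _prepare(trace: BPTrace, interval_s: float):
    dt = trace.dt
    if interval_s < dt - 1e-9:
        raise ConfigError(f"interval_s={interval_s} is below the native interval {dt} s")
    ratio = interval_s / dt
    if abs(ratio - round(ratio)) > 1e-9:
        raise ConfigError(
            f"interval_s={interval_s} must be an integer multiple of the native interval {dt} s"
        )
    step = int(round(ratio))
    n_bins = -(-trace.n // step)  # ceil(record duration / interval)
    bin_of = np.arange(trace.n) // step
    return step, n_bins, bin_of


def downsample_instantaneous(trace: BPTrace, interval_s: float) -> ResampledTrace:
    """Keep the first valid sample in each half-open bin; empty bins are invalid."""
    step, n_bins, bin_of = _prepare(trace, interval_s)
    cv = trace.clean_valid
    x_out = np.full(n_bins, np.nan)
    valid_out = np.zeros(n_bins, dtype=bool)
    vidx = np.flatnonzero(cv)
    if vidx.size:
        bins, first = np.unique(bin_of[vidx], return_index=True)
        x_out[bins] = trace.x[vidx[first]]
        valid_out[bins] = True
    t_out = trace.t[0] + np.arange(n_bins) * float(interval_s)
    return ResampledTrace(
        trace.patient_id, trace.channel, float(interval_s), "instantaneous",
        t_out, x_out, valid_out,
    )


def downsample_averaging(
    trace: BPTrace, interval_s: float, min_coverage: float = DEFAULT_MIN_COVERAGE
) -> ResampledTrace:
    """Mean of the valid samples in each bin; bins with coverage below
    ``min_coverage`` of their nominal sample count are invalid."""
    if not 0 < min_coverage <= 1:
        raise ConfigError("min_coverage must be in (0, 1]")
    step, n_bins, bin_of = _prepare(trace, interval_s)
    cv = trace.clean_valid
    expected = np.bincount(bin_of, minlength=n_bins).astype(float)
    counts = np.bincount(bin_of[cv], minlength=n_bins).astype(float)
    sums = np.bincount(bin_of[cv], weights=trace.x[cv], minlength=n_bins)
    valid_out = counts >= np.maximum(min_coverage * expected, 1.0)
    x_out = np.full(n_bins, np.nan)
    np.divide(sums, counts, out=x_out, where=valid_out)
    t_out = trace.t[0] + np.arange(n_bins) * float(interval_s)
    return ResampledTrace(
        trace.patient_id, trace.channel, float(interval_s), "averaging",
        t_out, x_out, valid_out,
    )


def downsample(
    trace: BPTrace,
    interval_s: float,
    method: str,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> ResampledTrace:
    """Dispatch to one of the two downsampling schemes."""
    if method == "instantaneous":
        return downsample_instantaneous(trace, interval_s)
    if method == "averaging":
        return downsample_averaging(trace, interval_s, min_coverage=min_coverage)
    raise ConfigError(f"method must be one of {METHODS}, got {method!r}")
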