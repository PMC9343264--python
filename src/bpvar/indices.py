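"""Time-domain blood-pressure-variability indices.

For a series ``BP = (BP_1, ..., BP_n)`` of consecutive measurements the
package computes, next to the mean:

* ``SD``  — sample standard deviation (1/(n-1) normalisation),
* ``CV``  — coefficient of variation, SD / mean,
* ``ARV`` — averaged real variability, the mean absolute successive
  difference ``1/(n-1) * sum |BP_{i+1} - BP_i|``,
* ``SV``  — successive variation, the root-mean-square successive
  difference ``sqrt(1/(n-1) * sum |BP_{i+1} - BP_i|^2)``,
* ``TC``  — relative number of trend changes, the fraction
  ``#[(BP_{i+1}-BP_i)*(BP_{i+2}-BP_{i+1}) < 0] / n`` of samples at which the
  successive difference strictly changes sign.

Under gaps and artifact masking, successive pairs (and TC's triples) are used
only when they lie within one contiguous valid segment and are not excluded
by the 3-SD difference mask; the ``n - 1`` denominator of ARV/SV is replaced
by the count of differences actually used, while TC keeps the total valid
sample count ``n`` in its denominator.  SV weighs frequencies close to the
(possibly downsampled) sampling frequency more strongly, which is why the
package pairs it with the averaging downsampler.

Indices that are undefined on a given input (too few samples, non-positive
mean for CV) are reported as NaN, never as 0 — zero variability is a
meaningful value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .resampling import DEFAULT_GRID, DEFAULT_MIN_COVERAGE, METHODS, downsample
from .traces import BPTrace, CleanTrace

logger = logging.getLogger(__name__)

INDEX_NAMES = ("mean", "sd", "cv", "arv", "sv", "tc")


@dataclass
class IndexSet:
    """The six per-trace scalars plus the sample counts behind them."""

    mean: float
    sd: float
    cv: float
    arv: float
    sv: float
    tc: float
    n: int
    n_diffs_used: int

    def as_dict(self) -> dict:
        return {
            "mean": self.mean, "sd": self.sd, "cv": self.cv,
            "arv": self.arv, "sv": self.sv, "tc": self.tc,
            "n": self.n, "n_diffs_used": self.n_diffs_used,
        }


def _resolve(series, diff_excluded):
    if isinstance(series, CleanTrace):
        x, valid = series.x, series.clean_valid
        if diff_excluded is None:
            diff_excluded = series.diff_excluded
    elif isinstance(series, BPTrace):
        x, valid = series.x, series.valid
    elif hasattr(series, "x") and hasattr(series, "valid"):  # ResampledTrace
        x, valid = np.asarray(series.x, float), np.asarray(series.valid, bool)
    else:
        x = np.asarray(series, dtype=float)
        valid = np.isfinite(x)
    if diff_excluded is None:
        diff_excluded = np.zeros(max(x.size - 1, 0), dtype=bool)
    return x, valid, np.asarray(diff_excluded, dtype=bool)


def compute_indices(series, diff_excluded: Optional[np.ndarray] = None) -> IndexSet:
    """All six statistics of a (possibly resampled, possibly gappy) series.

    ``series`` may be a CleanTrace (its own difference mask is used), a raw
    trace, a ResampledTrace, or a plain array.
    """
    x, valid, excl = _resolve(series, diff_excluded)
    n = int(valid.sum())
    if n == 0:
        raise DataError("no valid samples")
    xv = x[valid]
    mean = float(np.mean(xv))

    if n >= 2:
        sd = float(np.std(xv, ddof=1))
    else:
        sd = math.nan
        logger.info("sd undefined: n=%d < 2", n)
    if not math.isnan(sd) and mean > 0:
        cv = sd / mean
    else:
        cv = math.nan
        if mean <= 0:
            logger.info("cv undefined: mean %.3f is not positive", mean)

    d = np.diff(x)
    pair = valid[:-1] & valid[1:] & ~excl
    with np.errstate(invalid="ignore"):
        dd = d[pair]
    m = int(dd.size)
    if m >= 1:
        arv = float(np.mean(np.abs(dd)))
        sv = float(np.sqrt(np.mean(dd ** 2)))
    else:
        arv = sv = math.nan
        logger.info("arv/sv undefined: no usable successive differences")

    if n >= 3:
        tri = pair[:-1] & pair[1:]
        with np.errstate(invalid="ignore"):
            changes = tri & (d[:-1] * d[1:] < 0)
        tc = float(changes.sum()) / n
    else:
        tc = math.nan
        logger.info("tc undefined: n=%d < 3", n)

    return IndexSet(mean=mean, sd=sd, cv=cv, arv=arv, sv=sv, tc=tc, n=n, n_diffs_used=m)


def index_battery(
    trace: CleanTrace,
    intervals: Sequence[float] = DEFAULT_GRID,
    methods: Sequence[str] = METHODS,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """One IndexSet per (sampling interval, downsampling method) pair.

    At the native interval both methods reduce to the identity, so the row
    equals :func:`compute_indices` on the clean trace directly.
    """
    rows = []
    for interval in intervals:
        for method in methods:
            if np.isclose(interval, trace.dt):
                iset = compute_indices(trace)
            else:
                iset = compute_indices(downsample(trace, interval, method, min_coverage))
            rows.append({"interval_s": float(interval), "method": method, **iset.as_dict()})
    return pd.DataFrame(rows)
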